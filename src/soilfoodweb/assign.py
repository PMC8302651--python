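"""Assign MOTUs to trophic groups from their taxonomy and optional guild.

Matching is most-specific-wins: the deepest clade of a MOTU's taxonomy
that appears in the scheme's taxon lookup decides the group.  A guild
annotation (e.g. ``ectomycorrhizal`` for a fungal MOTU), when present,
overrides clade-only matches: guild-qualified lookup entries are searched
first, again deepest clade first.  MOTUs matching nothing at any rank go
to the unassigned partition and are excluded from all downstream
computation.  Matching is case-insensitive and whitespace-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import MotuTable, TrophicScheme


@dataclass
class AssignedTable:
    """A MotuTable partitioned into assigned and unassigned MOTUs.

    ``assignments`` is indexed by motu_id (assigned MOTUs only) with
    columns ``group_id``, ``class_id``, ``assignment_rank`` (0-based depth
    of the matching clade within the taxonomy) and ``matched_clade``.
    """

    table: MotuTable
    assignments: pd.DataFrame
    unassigned: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.assignments.index) & set(self.unassigned)
        if overlap:
            raise ValidationError(f"MOTU {next(iter(overlap))!r} both assigned and unassigned")

    @property
    def assigned_ids(self) -> list[str]:
        return list(self.assignments.index)

    def reads_by_group(self, per_marker: bool = False):
        """Sum assigned read counts to group x sample matrices.

        With ``per_marker=True`` returns ``{marker: DataFrame}`` so
        proportions can be taken within each amplicon's read pool.
        """
        counts = self.table.counts.loc[self.assignments.index]
        groups = self.assignments["group_id"]
        if not per_marker:
            return counts.groupby(groups).sum()
        markers = self.table.motus.loc[self.assignments.index, "marker"]
        return {
            m: sub.groupby(groups.loc[sub.index]).sum()
            for m, sub in counts.groupby(markers)
        }


def _normalize(s: str) -> str:
    return " ".join(str(s).strip().lower().split())


def assign_trophic_groups(table: MotuTable, scheme: TrophicScheme) -> AssignedTable:
    """Map each MOTU to a trophic group; unmatched MOTUs go unassigned."""
    guild_map: dict[tuple[str, str], str] = {}
    clade_map: dict[str, str] = {}
    for _, row in scheme.lookup.iterrows():
        clade = _normalize(row["clade"])
        guild = _normalize(row["guild"]) if row["guild"] else ""
        if guild:
            guild_map[(clade, guild)] = row["group"]
        else:
            clade_map[clade] = row["group"]

    g2c = scheme.group_to_class()
    records = []
    unassigned = []
    for motu_id in table.motu_ids:
        ranks = [_normalize(r) for r in table.taxonomy_list(motu_id)]
        guild = _normalize(table.motus.at[motu_id, "guild"])
        hit = None
        if guild:
            for depth in range(len(ranks) - 1, -1, -1):
                group = guild_map.get((ranks[depth], guild))
                if group is not None:
                    hit = (depth, group)
                    break
        if hit is None:
            for depth in range(len(ranks) - 1, -1, -1):
                group = clade_map.get(ranks[depth])
                if group is not None:
                    hit = (depth, group)
                    break
        if hit is None:
            unassigned.append(motu_id)
        else:
            depth, group = hit
            records.append(
                {"motu_id": motu_id, "group_id": group, "class_id": g2c[group],
                 "assignment_rank": depth,
                 "matched_clade": table.taxonomy_list(motu_id)[depth]}
            )
    assignments = pd.DataFrame(
        records, columns=["motu_id", "group_id", "class_id", "assignment_rank",
                          "matched_clade"]
    ).set_index("motu_id")
    return AssignedTable(table=table, assignments=assignments, unassigned=unassigned)


def assignment_summary(assigned: AssignedTable) -> pd.DataFrame:
    """Per-group totals over all samples: MOTUs, reads, log10 reads.

    Groups with zero reads keep their raw total but get NaN on the log
    scale (excluded from the log report).
    """
    counts = assigned.table.counts.loc[assigned.assignments.index]
    totals = counts.sum(axis=1).groupby(assigned.assignments["group_id"]).sum()
    n_motus = assigned.assignments.groupby("group_id").size()
    out = pd.DataFrame({"n_motus": n_motus, "total_reads": totals})
    out["log10_reads"] = np.where(out["total_reads"] > 0,
                                  np.log10(out["total_reads"].clip(lower=1)), np.nan)
    out.index.name = "group_id"
    return out.sort_index()
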