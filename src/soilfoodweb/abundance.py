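"""Per-sample, per-group MOTU diversity and double-transformed abundances.

Within-group MOTU diversity is the Hill-Shannon diversity (exponential of
Shannon entropy) of the group's MOTU read proportions in one sample — a
robust effective-richness measure for eDNA read data.  For comparisons
across groups it is standardized by each group's maximum across samples.

Relative abundances use the double transform: (1) each group's reads are
converted to a proportion within the sample, (2) proportions are rescaled
by the group's largest observed proportion across all samples, yielding
values from 0 (absent) to 1 (largest observed proportion).  Because the
three amplicons' read totals are not comparable, proportions are taken
within each marker's read pool by default (``per_marker=True``); a pooled
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .assign import AssignedTable
from .io import TrophicScheme


@dataclass
class GroupSampleMatrix:
    """Groups x samples value matrix tagged with its kind.

    ``kind`` is one of ``hill_diversity``, ``raw_proportion``,
    ``relative_abundance``, ``standardized_diversity``.  ``flags`` lists
    groups whose row could not be standardized (all-zero rows).
    """

    values: pd.DataFrame
    kind: str
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValidationError("group-sample values must be non-negative")
        if self.kind in ("relative_abundance", "standardized_diversity"):
            if (self.values.to_numpy(dtype=float) > 1 + 1e-12).any():
                raise ValidationError(f"{self.kind} values must lie in [0, 1]")


def motu_hill_diversity(reads) -> float:
    """Hill-Shannon diversity exp(-sum q ln q) of one group's MOTU reads.

    Returns 0.0 for an empty group (total reads zero); 1.0 for a single
    MOTU; the MOTU richness for perfectly even reads.
    """
    arr = np.asarray(reads, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative read count")
    total = arr.sum()
    if total == 0:
        return 0.0
    q = arr[arr > 0] / total
    return float(np.exp(-(q * np.log(q)).sum()))


def hill_diversity_matrix(assigned: AssignedTable) -> GroupSampleMatrix:
    """Per-sample Hill-Shannon MOTU diversity for every trophic group."""
    counts = assigned.table.counts.loc[assigned.assignments.index]
    groups = assigned.assignments["group_id"]
    rows = {}
    for g, sub in counts.groupby(groups):
        arr = sub.to_numpy(dtype=float)
        total = arr.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(total > 0, arr / np.where(total > 0, total, 1.0), 0.0)
            plogp = np.where(q > 0, q * np.log(q), 0.0)
        div = np.where(total > 0, np.exp(-plogp.sum(axis=0)), 0.0)
        rows[g] = div
    values = pd.DataFrame(rows, index=counts.columns).T.sort_index()
    values.index.name = "group_id"
    return GroupSampleMatrix(values=values, kind="hill_diversity")


def standardize_diversity(matrix: GroupSampleMatrix) -> GroupSampleMatrix:
    """Divide each group's row by its maximum across samples.

    All-zero rows are left at 0 and listed in ``flags``.
    """
    if matrix.kind != "hill_diversity":
        raise ValidationError("standardize_diversity expects a hill_diversity matrix")
    vals = matrix.values.copy().astype(float)
    rowmax = vals.max(axis=1)
    flags = list(rowmax.index[rowmax == 0])
    safe = rowmax.replace(0, 1.0)
    return GroupSampleMatrix(values=vals.div(safe, axis=0),
                             kind="standardized_diversity", flags=flags)


def group_relative_abundance(assigned: AssignedTable,
                             per_marker: bool = True) -> GroupSampleMatrix:
    """Double-transformed group relative abundances (values in [0, 1]).

    Step 1: group reads -> proportion of the sample's read pool (the
    marker's pool with ``per_marker=True``, the pooled total otherwise).
    Step 2: divide each group's proportions by the group's maximum
    proportion across samples.  A sample with zero assigned reads is an
    error naming the sample.
    """
    samples = assigned.table.samples
    total_assigned = assigned.table.counts.loc[assigned.assignments.index].sum(axis=0)
    empty = total_assigned.index[total_assigned == 0]
    if len(empty):
        raise ValidationError(f"sample {empty[0]!r} has zero assigned reads")

    if per_marker:
        pools = assigned.reads_by_group(per_marker=True)
        parts = []
        for marker, reads in pools.items():
            depth = reads.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                prop = reads.div(depth.replace(0, np.nan), axis=1).fillna(0.0)
            parts.append(prop)
        prop = pd.concat(parts).groupby(level=0).sum()
    else:
        reads = assigned.reads_by_group(per_marker=False)
        prop = reads.div(reads.sum(axis=0), axis=1)
    prop = prop.reindex(columns=samples).fillna(0.0)
    rowmax = prop.max(axis=1)
    flags = list(rowmax.index[rowmax == 0])
    out = prop.div(rowmax.replace(0, 1.0), axis=0).sort_index()
    out.index.name = "group_id"
    return GroupSampleMatrix(values=out, kind="relative_abundance", flags=flags)


def class_abundance(matrix: GroupSampleMatrix, scheme: TrophicScheme) -> GroupSampleMatrix:
    """Sum member-group relative abundances to the trophic-class level.

    Class values may exceed 1 (they are sums); no re-normalization here —
    local food-web induction normalizes within each web.
    """
    if matrix.kind != "relative_abundance":
        raise ValidationError("class_abundance expects a relative_abundance matrix")
    g2c = scheme.group_to_class()
    unknown = [g for g in matrix.values.index if g not in g2c]
    if unknown:
        raise ValidationError(f"group {unknown[0]!r} not in scheme")
    mapped = matrix.values.groupby(pd.Series(g2c).reindex(matrix.values.index)).sum()
    mapped.index.name = "class_id"
    return GroupSampleMatrix(values=mapped, kind="class_abundance")
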