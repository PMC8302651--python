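"""Domain types and readers/writers for the tabular and graph formats of the pipeline.

The pipeline starts from a curated MOTU-by-sample read-count table (one row
per Molecular Operational Taxonomic Unit) together with sample metadata
describing the nested sampling design (soil cores within stations within
areas, half of the stations defoliated).  A packaged trophic scheme maps
taxonomic clades to 37 fine trophic groups nested in 9 broad trophic
classes and carries the per-group traits (body-size rank, micro/macro
scale, endoparasite flag, resource links, feeding preferences) that drive
metaweb construction.

File conventions
----------------
* MOTU table: TSV with columns ``motu_id, marker, taxonomy, [guild,]
  <sample_1>, ..., <sample_n>``; taxonomy is an ordered rank list joined
  by ``;`` (kingdom first, ranks may be missing below some level).
* Sample metadata: CSV ``sample_id, station, area, defoliation`` with
  defoliation coded 0 (undamaged) / 1 (defoliated).
* Scheme fixtures: ``groups.csv`` (group, class, traits) and
  ``taxon_lookup.csv`` (clade, rank, guild, group).
* Metaweb: square CSV adjacency (rows = prey, columns = consumers;
  edges point prey -> consumer, i.e. energy flow).
* Web exports: single-file edge-list TSV (node and edge records) or
  GraphML.

All text files are UTF-8; delimiters are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

RESOURCE_NODES = ("sunlight", "organic_matter", "plants")

_MOTU_META_COLS = ("motu_id", "marker", "taxonomy")


def _split_taxonomy(tax: str) -> list[str]:
    return [t.strip() for t in str(tax).split(";") if t.strip()]


# ---------------------------------------------------------------------------
# MotuTable
# ---------------------------------------------------------------------------


@dataclass
class MotuTable:
    """Samples x MOTUs read counts plus per-MOTU annotations.

    Attributes
    ----------
    counts : DataFrame
        Integer read counts, index = motu_id, columns = sample ids.
    motus : DataFrame
        Per-MOTU annotations, index = motu_id, columns ``marker``,
        ``taxonomy`` (semicolon-joined rank list) and ``guild``
        (empty string when absent).
    """

    counts: pd.DataFrame
    motus: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate motu_id {dup!r}")
        if not self.counts.index.equals(self.motus.index):
            raise ValidationError("counts and motus index mismatch")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric read counts")
        bad = np.argwhere(arr < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative read count at motu {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if "guild" not in self.motus.columns:
            self.motus = self.motus.assign(guild="")
        self.motus["guild"] = self.motus["guild"].fillna("")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def motu_ids(self) -> list[str]:
        return list(self.counts.index)

    def taxonomy_list(self, motu_id: str) -> list[str]:
        return _split_taxonomy(self.motus.at[motu_id, "taxonomy"])

    def zero_read_motus(self) -> list[str]:
        """MOTUs with zero total reads (retained but flagged)."""
        total = self.counts.sum(axis=1)
        return list(total.index[total == 0])

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, MotuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.motus[
            ["marker", "taxonomy", "guild"]
        ].equals(other.motus[["marker", "taxonomy", "guild"]])


def read_motu_table(path, delimiter: str = "\t") -> MotuTable:
    """Read a MOTU table from a delimited text file.

    Raises :class:`ParseError` on malformed rows (with line number) and
    :class:`ValidationError` on invariant violations (duplicate ids,
    negative counts — the message names the offending cell).
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"motu_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in _MOTU_META_COLS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    meta_cols = [c for c in ("motu_id", "marker", "taxonomy", "guild") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns found")
    counts = df[sample_cols].copy()
    for col in sample_cols:
        converted = pd.to_numeric(counts[col], errors="coerce")
        bad = converted.isna() & counts[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric count in column {col!r}, line {line}")
        if (converted.dropna() % 1 != 0).any():
            raise ParseError(f"{path}: non-integer count in column {col!r}")
        counts[col] = converted.fillna(0).astype(np.int64)
    counts.index = pd.Index(df["motu_id"], name="motu_id")
    motus = df[meta_cols].set_index("motu_id")
    if "guild" not in motus.columns:
        motus["guild"] = ""
    return MotuTable(counts=counts, motus=motus)


def write_motu_table(table: MotuTable, path, delimiter: str = "\t") -> None:
    out = table.motus[["marker", "taxonomy", "guild"]].join(table.counts)
    out.to_csv(path, sep=delimiter, index=True, index_label="motu_id")


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample design information: station nested in area, defoliation 0/1."""

    table: pd.DataFrame  # columns sample_id, station, area, defoliation

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"sample_id", "station", "area", "defoliation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        if not set(self.table["defoliation"].unique()) <= {0, 1}:
            raise ValidationError("defoliation must be coded 0/1")
        # stations nest uniquely within areas
        by_station = self.table.groupby("station")
        if (by_station["area"].nunique() > 1).any():
            raise ValidationError("a station spans more than one area")
        if (by_station["defoliation"].nunique() > 1).any():
            raise ValidationError("defoliation not constant within a station")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition(self) -> pd.Series:
        """Defoliation dummy indexed by sample_id."""
        return self.table.set_index("sample_id")["defoliation"]

    def stations(self) -> pd.DataFrame:
        """One row per station: area and defoliation condition."""
        return (
            self.table.groupby("station", sort=True)
            .agg(area=("area", "first"), defoliation=("defoliation", "first"))
            .reset_index()
        )


def read_sample_metadata(path, delimiter: str = ",") -> SampleMetadata:
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str, "station": str, "area": str})
    if "defoliation" in df.columns:
        df["defoliation"] = df["defoliation"].astype(int)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path, delimiter: str = ",") -> None:
    meta.table.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# TrophicScheme
# ---------------------------------------------------------------------------

_BOOL_TRAITS = ("endoparasite", "cross_scale_feeder", "size_exception")
_LIST_TRAITS = ("resource_links", "prey", "avoid")


@dataclass
class TrophicScheme:
    """Trophic classification scheme: groups, classes, lookup and traits.

    ``groups`` is indexed by group_id with columns:

    ``class_id``            broad trophic class of the group
    ``size_rank``           ordinal body-size rank (1 = smallest)
    ``organism_scale``      ``micro`` or ``macro``
    ``endoparasite``        strict (plant) endoparasite, never free-living prey
    ``cross_scale_feeder``  macro group allowed to consume micro prey
                            (or vice versa); encodes the enumerated
                            exceptions to the micro/macro separation rule
    ``size_exception``      consumer may take prey larger than itself
                            (animal parasites, omnivore nematodes)
    ``resource_links``      subset of sunlight/organic_matter/plants (;-joined)
    ``prey``                feeding whitelist of group_ids (;-joined)
    ``avoid``               feeding blacklist of group_ids (;-joined)

    ``lookup`` maps taxonomic clade names (optionally refined by a guild
    annotation) to group_ids; matching is case-insensitive.
    """

    groups: pd.DataFrame
    lookup: pd.DataFrame  # columns clade, rank, guild, group

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.groups.index.duplicated().any():
            dup = self.groups.index[self.groups.index.duplicated()][0]
            raise ValidationError(f"group {dup!r} defined more than once")
        if self.groups["class_id"].isna().any():
            g = self.groups.index[self.groups["class_id"].isna()][0]
            raise ValidationError(f"group {g!r} has no class")
        known = set(self.groups.index)
        for col in ("prey", "avoid"):
            for g, val in self.groups[col].items():
                for ref in self._split(val):
                    if ref not in known:
                        raise ValidationError(
                            f"group {g!r} {col} references unknown group {ref!r}"
                        )
        for g, val in self.groups["resource_links"].items():
            for ref in self._split(val):
                if ref not in RESOURCE_NODES:
                    raise ValidationError(f"group {g!r} links unknown resource {ref!r}")
        bad = ~self.lookup["group"].isin(known)
        if bad.any():
            ref = self.lookup.loc[bad, "group"].iloc[0]
            raise ValidationError(f"taxon lookup references unknown group {ref!r}")
        # conflicting lookups: same (clade, guild) key mapping to two groups
        key = self.lookup.assign(
            _clade=self.lookup["clade"].str.strip().str.lower(),
            _guild=self.lookup["guild"].fillna("").str.strip().str.lower(),
        )
        dup = key.groupby(["_clade", "_guild"])["group"].nunique()
        conflicts = dup[dup > 1]
        if len(conflicts):
            clade = conflicts.index[0][0]
            raise ValidationError(f"ambiguous taxon lookup for clade {clade!r}")

    @staticmethod
    def _split(val) -> list[str]:
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return []
        return [v.strip() for v in str(val).split(";") if v.strip()]

    @property
    def group_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def class_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.groups["class_id"]:
            seen.setdefault(c, None)
        return list(seen)

    def group_to_class(self) -> dict[str, str]:
        return dict(self.groups["class_id"])

    def class_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.class_ids}
        for g, c in self.groups["class_id"].items():
            out[c].append(g)
        return out

    def trait(self, group: str, name: str):
        return self.groups.at[group, name]

    def prey_of(self, group: str) -> list[str]:
        return self._split(self.groups.at[group, "prey"])

    def avoid_of(self, group: str) -> list[str]:
        return self._split(self.groups.at[group, "avoid"])

    def resources_of(self, group: str) -> list[str]:
        return self._split(self.groups.at[group, "resource_links"])


def read_trophic_scheme(groups_path=None, lookup_path=None) -> TrophicScheme:
    """Load a trophic scheme; defaults to the packaged 37-group / 9-class fixture."""
    if groups_path is None:
        groups_path = resources.files("soilfoodweb.data") / "groups.csv"
    if lookup_path is None:
        lookup_path = resources.files("soilfoodweb.data") / "taxon_lookup.csv"
    groups = pd.read_csv(groups_path, dtype=str).set_index("group")
    for col in _BOOL_TRAITS:
        groups[col] = groups[col].fillna("0").map(
            lambda v: str(v).strip().lower() in {"1", "true", "yes"}
        )
    groups["size_rank"] = groups["size_rank"].astype(int)
    for col in _LIST_TRAITS:
        if col not in groups.columns:
            groups[col] = ""
        groups[col] = groups[col].fillna("")
    lookup = pd.read_csv(lookup_path, dtype=str)
    lookup["guild"] = lookup.get("guild", pd.Series(dtype=str)).fillna("")
    return TrophicScheme(groups=groups, lookup=lookup)


def default_scheme() -> TrophicScheme:
    return read_trophic_scheme()


# ---------------------------------------------------------------------------
# Metaweb
# ---------------------------------------------------------------------------


@dataclass
class Metaweb:
    """Directed potential-interaction network over trophic groups or classes.

    ``adjacency`` is a square DataFrame, rows = prey, columns = consumers;
    entries are 0/1 at group resolution and interaction probabilities in
    [0, 1] at class resolution.  Resource nodes (sunlight, organic matter,
    plants) are structural: they may feed consumers but have no incoming
    links and are excluded from diversity analyses.
    """

    adjacency: pd.DataFrame
    resolution: str = "group"
    resource_nodes: tuple = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        adj = self.adjacency
        if not adj.index.equals(adj.columns):
            raise ValidationError("metaweb adjacency must be square with matching labels")
        vals = adj.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("metaweb adjacency entries must lie in [0, 1]")
        if self.resolution == "group" and not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("group-level metaweb must be binary")
        diag = np.diag(vals)
        if self.resolution == "group" and diag.any():
            node = adj.index[int(np.flatnonzero(diag)[0])]
            raise ValidationError(f"self-link at group {node!r}")
        for r in self.resource_nodes:
            if r in adj.columns and vals[:, adj.columns.get_loc(r)].any():
                raise ValidationError(f"resource node {r!r} has incoming links")

    @property
    def nodes(self) -> list[str]:
        return list(self.adjacency.index)

    @property
    def organism_nodes(self) -> list[str]:
        return [n for n in self.adjacency.index if n not in self.resource_nodes]

    def links(self) -> list[tuple[str, str]]:
        """Directed (prey, consumer) pairs with positive weight."""
        adj = self.adjacency.to_numpy(dtype=float)
        rows, cols = np.nonzero(adj > 0)
        idx = self.adjacency.index
        return [(idx[i], idx[j]) for i, j in zip(rows, cols)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Metaweb):
            return NotImplemented
        return (
            self.resolution == other.resolution
            and tuple(self.resource_nodes) == tuple(other.resource_nodes)
            and self.adjacency.index.equals(other.adjacency.index)
            and np.allclose(self.adjacency.to_numpy(float), other.adjacency.to_numpy(float))
        )


def read_metaweb(path=None, resolution: str = "group",
                 resource_nodes: Iterable[str] = RESOURCE_NODES) -> Metaweb:
    """Read a square CSV adjacency; defaults to the packaged group metaweb."""
    if path is None:
        path = resources.files("soilfoodweb.data") / "metaweb_groups.csv"
    adj = pd.read_csv(path, index_col=0)
    adj.index = adj.index.astype(str)
    adj.columns = adj.columns.astype(str)
    present = tuple(r for r in resource_nodes if r in adj.index)
    return Metaweb(adjacency=adj.astype(float), resolution=resolution,
                   resource_nodes=present)


def write_metaweb(web: Metaweb, path) -> None:
    out = web.adjacency.copy()
    if web.resolution == "group":
        out = out.astype(int)
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Generic web export (edge-list TSV / GraphML)
# ---------------------------------------------------------------------------


def _web_graph(web) -> nx.DiGraph:
    """Build a DiGraph from a Metaweb or LocalWeb (duck-typed)."""
    g = nx.DiGraph()
    if isinstance(web, Metaweb):
        for n in web.nodes:
            g.add_node(n, weight=1.0)
        for prey, consumer in web.links():
            g.add_edge(prey, consumer, weight=float(web.adjacency.at[prey, consumer]))
    else:  # LocalWeb
        for n, w in web.node_weights.items():
            g.add_node(n, weight=float(w))
        for _, row in web.links.iterrows():
            g.add_edge(row["prey"], row["consumer"], weight=float(row["weight"]))
    return g


def export_web(web, path, format: str = "edgelist") -> None:
    """Export a web to ``edgelist`` (single-file TSV) or ``graphml``.

    The edge-list TSV has columns ``record, id, target, weight``: one
    ``node`` record per node (weight = node weight) and one ``edge``
    record per directed prey -> consumer link.  An empty web therefore
    yields a file with node records only.
    """
    g = _web_graph(web)
    if format == "graphml":
        nx.write_graphml(g, path)
        return
    if format != "edgelist":
        raise ValueError(f"unknown export format {format!r}")
    rows = [{"record": "node", "id": n, "target": "", "weight": d["weight"]}
            for n, d in g.nodes(data=True)]
    rows += [{"record": "edge", "id": u, "target": v, "weight": d["weight"]}
             for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["record", "id", "target", "weight"]).to_csv(
        path, sep="\t", index=False)


def import_web_edgelist(path) -> nx.DiGraph:
    """Re-import an edge-list TSV written by :func:`export_web`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "target": str},
                     keep_default_na=False)
    g = nx.DiGraph()
    for _, row in df.iterrows():
        if row["record"] == "node":
            g.add_node(row["id"], weight=float(row["weight"]))
        elif row["record"] == "edge":
            g.add_edge(row["id"], row["target"], weight=float(row["weight"]))
        else:
            raise ParseError(f"{path}: unknown record type {row['record']!r}")
    return g


# ---------------------------------------------------------------------------
# EffectTable
# ---------------------------------------------------------------------------

EFFECT_COLUMNS = ("group_id", "response", "effect", "ci_low", "ci_high", "rhat", "method")


def validate_effect_table(table: pd.DataFrame) -> None:
    missing = set(EFFECT_COLUMNS[:5]) - set(table.columns)
    if missing:
        raise ValidationError(f"effect table missing columns {sorted(missing)}")
    bad = (table["ci_low"] > table["effect"]) | (table["effect"] > table["ci_high"])
    if bad.any():
        g = table.loc[bad, "group_id"].iloc[0]
        raise ValidationError(f"interval does not bracket the estimate for {g!r}")
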