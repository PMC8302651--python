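"""Per-sample local food webs realized from the metaweb.

At the trophic-group resolution a local web keeps the groups detected in
the sample (double-transformed relative abundance > 0) as nodes, weighted
by that abundance; a metaweb link is realized (binary) when both
endpoints are present.  At the trophic-class resolution node weights are
member-group abundance sums normalized to 1 within the web, and links
carry the probability that a random encounter between members of the two
classes is a feeding interaction:

    W_kl = sum_{i in k, j in l} p_i p_j pi_ij / sum_{i in k, j in l} p_i p_j

with sums over locally present groups (i != j) and pi the binary group
metaweb.  Resource nodes are structural and excluded throughout.

The link-abundance distribution ``L`` used by the network-diversity
metrics weights each realized link by the product of its endpoint
abundances (an encounter proxy), normalized to sum 1 over links; a
uniform-over-links alternative is available (``mode='uniform'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Metaweb, SampleMetadata, TrophicScheme

_TOL = 1e-9


@dataclass
class LocalWeb:
    sample_id: str
    resolution: str  # 'group' | 'class'
    node_weights: pd.Series  # p[node] > 0
    links: pd.DataFrame  # columns prey, consumer, weight

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p = self.node_weights.to_numpy(dtype=float)
        if (p <= 0).any():
            node = self.node_weights.index[int(np.flatnonzero(p <= 0)[0])]
            raise ValidationError(f"non-positive node weight at {node!r}")
        if self.resolution == "class" and len(p) and abs(p.sum() - 1.0) > _TOL:
            raise ValidationError("class node weights must sum to 1")
        if len(self.links):
            w = self.links["weight"].to_numpy(dtype=float)
            if ((w < 0) | (w > 1)).any():
                raise ValidationError("link weights must lie in [0, 1]")
            for col in ("prey", "consumer"):
                missing = ~self.links[col].isin(self.node_weights.index)
                if missing.any():
                    raise ValidationError(
                        f"link endpoint {self.links.loc[missing, col].iloc[0]!r} "
                        "is not a node")

    @property
    def n_nodes(self) -> int:
        return len(self.node_weights)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def link_abundances(self, mode: str = "encounter") -> pd.Series:
        """Distribution L over realized links (sums to 1); see module docs."""
        return link_abundance_distribution(self, mode=mode)


def _empty_links() -> pd.DataFrame:
    return pd.DataFrame(columns=["prey", "consumer", "weight"])


def induce_group_web(metaweb: Metaweb, abundances: pd.Series,
                     sample_id: str = "") -> LocalWeb:
    """Realize the group-level local web of one sample.

    ``abundances`` is the sample's column of the double-transformed
    relative-abundance matrix, indexed by group.  Nodes are groups with
    abundance > 0; a link is present iff the metaweb has it and both
    endpoints are present.  Resource nodes are excluded.
    """
    if metaweb.resolution != "group":
        raise ValidationError("induce_group_web needs a group-resolution metaweb")
    groups = [g for g in metaweb.organism_nodes if g in abundances.index]
    p = abundances.loc[groups].astype(float)
    p = p[p > 0]
    present = set(p.index)
    rows = [
        {"prey": prey, "consumer": cons, "weight": 1.0}
        for prey, cons in metaweb.links()
        if prey in present and cons in present
    ]
    links = pd.DataFrame(rows, columns=["prey", "consumer", "weight"])
    return LocalWeb(sample_id=sample_id, resolution="group",
                    node_weights=p, links=links)


def link_abundance_distribution(web: LocalWeb, mode: str = "encounter") -> pd.Series:
    """L over the web's links: encounter products p_i * p_j (default) or
    uniform mass per link; normalized to sum 1.  Errors when linkless."""
    if web.n_links == 0:
        raise ValidationError(
            f"web {web.sample_id!r} has no links; link distribution undefined")
    p = web.node_weights
    if mode == "encounter":
        raw = (p.loc[web.links["prey"]].to_numpy()
               * p.loc[web.links["consumer"]].to_numpy()
               * web.links["weight"].to_numpy(dtype=float))
    elif mode == "uniform":
        raw = np.ones(web.n_links)
    else:
        raise ValueError(f"unknown link-abundance mode {mode!r}")
    idx = pd.MultiIndex.from_frame(web.links[["prey", "consumer"]])
    return pd.Series(raw / raw.sum(), index=idx, name="L")


def induce_class_web(web: LocalWeb, scheme: TrophicScheme) -> LocalWeb:
    """Aggregate a group-level local web to the trophic-class resolution."""
    if web.resolution != "group":
        raise ValidationError("induce_class_web needs a group-resolution web")
    g2c = scheme.group_to_class()
    p = web.node_weights
    classes = pd.Series({g: g2c[g] for g in p.index})
    class_p = p.groupby(classes).sum()
    class_p = class_p / class_p.sum() if len(class_p) else class_p

    # encounter mass per ordered class pair: sum of p_i p_j over present
    # member pairs (i != j); linked mass from the realized group links
    members: dict[str, pd.Series] = {c: p[classes == c] for c in class_p.index}
    linked = {}
    for _, row in web.links.iterrows():
        key = (g2c[row["prey"]], g2c[row["consumer"]])
        linked[key] = linked.get(key, 0.0) + p[row["prey"]] * p[row["consumer"]]
    rows = []
    for k, pk in members.items():
        for l, pl in members.items():
            den = float(pk.sum() * pl.sum())
            if k == l:
                den -= float((pk ** 2).sum())
            if den <= 0:
                continue  # no encounter mass: link weight undefined -> absent
            num = linked.get((k, l), 0.0)
            if num > 0:
                rows.append({"prey": k, "consumer": l,
                             "weight": min(num / den, 1.0)})
    links = pd.DataFrame(rows, columns=["prey", "consumer", "weight"])
    return LocalWeb(sample_id=web.sample_id, resolution="class",
                    node_weights=class_p, links=links)


def class_proportion_change(webs: list[LocalWeb], metadata: SampleMetadata):
    """Mean class proportions and link weights by condition, plus change.

    Returns ``(node_change, link_change)`` DataFrames with columns
    ``undamaged``, ``defoliated`` and ``change`` (= defoliated -
    undamaged).  A class (or link) absent from a web contributes 0 to that
    web's value, so means are over all webs of the condition.
    """
    cond = metadata.condition()
    if set(cond.unique()) != {0, 1}:
        raise ValidationError("need at least one web per condition")
    node_rows, link_rows = {}, {}
    for web in webs:
        if web.resolution != "class":
            raise ValidationError("class_proportion_change expects class webs")
        node_rows[web.sample_id] = web.node_weights
        link_rows[web.sample_id] = web.links.set_index(["prey", "consumer"])["weight"]
    nodes = pd.DataFrame(node_rows).T.fillna(0.0)
    links = pd.DataFrame(link_rows).T.fillna(0.0)

    def _summary(df: pd.DataFrame) -> pd.DataFrame:
        c = cond.loc[df.index]
        und = df[c == 0].mean(axis=0)
        defo = df[c == 1].mean(axis=0)
        return pd.DataFrame({"undamaged": und, "defoliated": defo,
                             "change": defo - und})

    return _summary(nodes), _summary(links)
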