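"""Hill-number diversity and dissimilarity of local food webs.

Diversity of order ``eta`` (the viewpoint parameter) of a probability
distribution q is the Hill number

    D_eta(q) = (sum_i q_i^eta)^(1/(1-eta)),   eta != 1
    D_1(q)   = exp(-sum_i q_i ln q_i)         (limit at eta = 1),

the effective number of equally-common elements.  ``eta`` tunes the
weight given to rare vs. abundant elements: eta -> 0 counts presence
(richness), eta = 1 is the exponential of Shannon entropy, eta = 2 the
inverse Simpson concentration.  Node diversity A^eta(p) applies this to a
web's node-abundance distribution, link diversity A^eta(L) to its
link-abundance distribution.

Across webs, alpha-diversity is the generalized mean with exponent
(1 - eta) of the local diversities (the geometric mean at eta = 1).  The
pairwise dissimilarity of two webs embeds both distributions in their
union node/link space, computes gamma (Hill number of the equal-weight
mixture), alpha-bar (generalized mean of the two local diversities) and
beta = gamma / alpha-bar in [1, 2], and normalizes to [0, 1]:

    dissimilarity = ln(beta) / ln(2)                         at eta = 1
    dissimilarity = (beta^(1-eta) - 1) / (2^(1-eta) - 1)     otherwise,

a Sorensen/Horn-type overlap complement: 0 for identical webs, 1 for
webs with disjoint support.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .localweb import LocalWeb

_ETA_TOL = 1e-9


def hill_number(weights, eta: float = 1.0) -> float:
    """Effective number of elements of a non-negative weight vector.

    Weights are normalized to probabilities internally; zero entries are
    ignored (order-eta diversity of a distribution never counts
    zero-mass elements).
    """
    if eta <= 0:
        raise ValidationError("viewpoint parameter eta must be > 0")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("all-zero weight vector has undefined diversity")
    q = w[w > 0] / total
    if abs(eta - 1.0) < _ETA_TOL:
        return float(np.exp(-(q * np.log(q)).sum()))
    return float((q ** eta).sum() ** (1.0 / (1.0 - eta)))


def node_diversity(web: LocalWeb, eta: float = 1.0) -> float:
    """A^eta(p): Hill diversity of the web's node weights."""
    if web.n_nodes == 0:
        raise ValidationError(f"web {web.sample_id!r} is empty")
    return hill_number(web.node_weights.to_numpy(), eta)


def link_diversity(web: LocalWeb, eta: float = 1.0, mode: str = "encounter") -> float:
    """A^eta(L): Hill diversity of the web's link-abundance distribution."""
    return hill_number(web.link_abundances(mode=mode).to_numpy(), eta)


def _generalized_mean(values, eta: float) -> float:
    v = np.asarray(values, dtype=float)
    if abs(eta - 1.0) < _ETA_TOL:
        return float(np.exp(np.mean(np.log(v))))
    ex = 1.0 - eta
    return float(np.mean(v ** ex) ** (1.0 / ex))


def alpha_diversity(webs, eta: float = 1.0, component: str = "nodes",
                    mode: str = "encounter") -> float:
    """Generalized mean (exponent 1 - eta) of the webs' local diversities.

    ``component`` selects node (``nodes``) or link (``links``) diversity;
    at eta = 1 this is the geometric mean.
    """
    if not len(webs):
        raise ValidationError("alpha_diversity needs at least one web")
    if component == "nodes":
        local = [node_diversity(w, eta) for w in webs]
    elif component == "links":
        local = [link_diversity(w, eta, mode=mode) for w in webs]
    else:
        raise ValueError(f"unknown component {component!r}")
    return _generalized_mean(local, eta)


def _distribution(web: LocalWeb, component: str, mode: str) -> pd.Series | None:
    if component == "nodes":
        p = web.node_weights
        if len(p) == 0:
            return None
        return p / p.sum()
    if web.n_links == 0:
        return None
    return web.link_abundances(mode=mode)


def pair_dissimilarity(q1: pd.Series, q2: pd.Series, eta: float = 1.0) -> float:
    """Dissimilarity of two distributions embedded in their union space."""
    union = q1.index.union(q2.index)
    a = q1.reindex(union).fillna(0.0).to_numpy()
    b = q2.reindex(union).fillna(0.0).to_numpy()
    gamma = hill_number((a + b) / 2.0, eta)
    alpha = _generalized_mean([hill_number(a, eta), hill_number(b, eta)], eta)
    beta = max(gamma / alpha, 1.0)
    if abs(eta - 1.0) < _ETA_TOL:
        d = np.log(beta) / np.log(2.0)
    else:
        ex = 1.0 - eta
        d = (beta ** ex - 1.0) / (2.0 ** ex - 1.0)
    return float(min(max(d, 0.0), 1.0))


def network_dissimilarity(webs, eta: float = 1.0, component: str = "nodes",
                          mode: str = "encounter") -> pd.DataFrame:
    """Pairwise dissimilarity matrix over webs (symmetric, zero diagonal).

    Pairs where one web is empty for the chosen component are recorded as
    missing (NaN), not 0 or 1.
    """
    if len(webs) < 2:
        raise ValidationError("network_dissimilarity needs at least two webs")
    ids = [w.sample_id for w in webs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids among webs")
    dists = [_distribution(w, component, mode) for w in webs]
    n = len(webs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if dists[i] is None or dists[j] is None:
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = pair_dissimilarity(dists[i], dists[j], eta)
        if dists[i] is None:
            out[i, i] = np.nan
    return pd.DataFrame(out, index=ids, columns=ids)
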