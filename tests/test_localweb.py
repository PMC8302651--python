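import numpy as np
import pandas as pd
import pytest

from soilfoodweb import (class_proportion_change, induce_class_web,
                         induce_group_web)
from soilfoodweb.errors import ValidationError
from soilfoodweb.io import Metaweb, SampleMetadata
from soilfoodweb.localweb import LocalWeb, link_abundance_distribution

from conftest import random_group_web, scheme_from_classmap


def tiny_metaweb():
    nodes = ["a", "b", "c"]
    adj = pd.DataFrame(0.0, index=pd.Index(nodes, name="prey"), columns=nodes)
    adj.at["a", "c"] = 1.0
    adj.at["b", "c"] = 1.0
    return Metaweb(adjacency=adj, resolution="group", resource_nodes=())


def test_induce_empty_and_minimal():
    web = tiny_metaweb()
    empty = induce_group_web(web, pd.Series({"a": 0.0, "b": 0.0, "c": 0.0}), "e")
    assert empty.n_nodes == 0 and empty.n_links == 0
    two = induce_group_web(web, pd.Series({"a": 0.5, "b": 0.0, "c": 0.3}), "t")
    assert two.n_nodes == 2 and two.n_links == 1
    assert two.links.iloc[0].tolist() == ["a", "c", 1.0]


def test_induction_matches_bruteforce_filter(metaweb, rel_abund):
    sample = rel_abund.values.columns[0]
    col = rel_abund.values[sample]
    web = induce_group_web(metaweb, col, sample)
    present = set(col.index[col > 0]) & set(metaweb.organism_nodes)
    expected = {(p, c) for p, c in metaweb.links()
                if p in present and c in present}
    got = set(map(tuple, web.links[["prey", "consumer"]].to_numpy()))
    assert got == expected
    assert set(web.node_weights.index) == present


def test_link_abundances_examples():
    web = tiny_metaweb()
    lw = induce_group_web(web, pd.Series({"a": 0.2, "b": 0.6, "c": 0.2}), "x")
    L = lw.link_abundances()
    assert L[("a", "c")] == pytest.approx(0.25)
    assert L[("b", "c")] == pytest.approx(0.75)
    assert L.sum() == pytest.approx(1.0)
    # uniform alternative ignores endpoint weights
    assert (lw.link_abundances(mode="uniform") == 0.5).all()
    single = induce_group_web(web, pd.Series({"a": 0.2, "b": 0.0, "c": 0.9}), "y")
    assert single.link_abundances().iloc[0] == pytest.approx(1.0)


def test_linkless_web_has_no_distribution():
    web = LocalWeb(sample_id="z", resolution="group",
                   node_weights=pd.Series({"a": 0.4}),
                   links=pd.DataFrame(columns=["prey", "consumer", "weight"]))
    with pytest.raises(ValidationError, match="no links"):
        link_abundance_distribution(web)


def test_class_link_probability_worked_example():
    # p(a)=0.2, p(b)=0.6 in class X; p(c)=0.2 in class Y; a->c linked only
    nodes = ["a", "b", "c"]
    adj = pd.DataFrame(0.0, index=pd.Index(nodes, name="prey"), columns=nodes)
    adj.at["a", "c"] = 1.0  # pi_ac = 1, pi_bc = 0
    web = Metaweb(adjacency=adj, resolution="group", resource_nodes=())
    lw = induce_group_web(web, pd.Series({"a": 0.2, "b": 0.6, "c": 0.2}), "x")
    scheme = scheme_from_classmap({"a": "X", "b": "X", "c": "Y"})
    cw = induce_class_web(lw, scheme)
    w = cw.links.set_index(["prey", "consumer"])["weight"]
    assert w[("X", "Y")] == pytest.approx(0.04 / 0.16)
    assert cw.node_weights["X"] == pytest.approx(0.8)
    assert cw.node_weights["Y"] == pytest.approx(0.2)


def test_class_link_probability_certain_event():
    nodes = ["a", "b", "c"]
    adj = pd.DataFrame(0.0, index=pd.Index(nodes, name="prey"), columns=nodes)
    adj.at["a", "c"] = adj.at["b", "c"] = 1.0
    web = Metaweb(adjacency=adj, resolution="group", resource_nodes=())
    lw = induce_group_web(web, pd.Series({"a": 0.3, "b": 0.3, "c": 0.4}), "x")
    scheme = scheme_from_classmap({"a": "X", "b": "X", "c": "Y"})
    cw = induce_class_web(lw, scheme)
    w = cw.links.set_index(["prey", "consumer"])["weight"]
    assert w[("X", "Y")] == pytest.approx(1.0)
    assert ("Y", "X") not in w.index  # no linked pairs -> link absent


def test_class_web_oracle_equivalence():
    """Class node weights and link probabilities match exhaustive
    double-loop enumeration on random small webs."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        web, classes, adj = random_group_web(rng)
        scheme = scheme_from_classmap(classes)
        cw = induce_class_web(web, scheme)
        p = web.node_weights
        groups = list(p.index)
        # brute-force enumeration
        cls = sorted(set(classes.values()))
        sums = {c: sum(p[g] for g in groups if classes[g] == c) for c in cls}
        total = sum(sums.values())
        linkset = {(r["prey"], r["consumer"]) for _, r in web.links.iterrows()}
        for c in cls:
            assert cw.node_weights[c] == pytest.approx(sums[c] / total, abs=1e-12)
        wmap = cw.links.set_index(["prey", "consumer"])["weight"]
        for ck in cls:
            for cl in cls:
                num = den = 0.0
                for i in groups:
                    for j in groups:
                        if i == j or classes[i] != ck or classes[j] != cl:
                            continue
                        den += p[i] * p[j]
                        if (i, j) in linkset:
                            num += p[i] * p[j]
                if den > 0 and num > 0:
                    assert wmap[(ck, cl)] == pytest.approx(num / den, abs=1e-12)
                else:
                    assert (ck, cl) not in wmap.index


def test_class_weights_sum_to_one_and_bounded():
    rng = np.random.default_rng(11)
    for _ in range(100):
        web, classes, _ = random_group_web(rng)
        cw = induce_class_web(web, scheme_from_classmap(classes))
        assert cw.node_weights.sum() == pytest.approx(1.0, abs=1e-9)
        if len(cw.links):
            assert cw.links["weight"].between(0, 1).all()


def test_induction_monotone_in_presence(metaweb, rel_abund):
    """Adding a present group never removes nodes or links."""
    sample = rel_abund.values.columns[0]
    col = rel_abund.values[sample].copy()
    absent = col.index[col == 0]
    if len(absent) == 0:
        pytest.skip("no absent group in this sample")
    before = induce_group_web(metaweb, col, "a")
    col[absent[0]] = 0.5
    after = induce_group_web(metaweb, col, "b")
    assert set(before.node_weights.index) <= set(after.node_weights.index)
    b = set(map(tuple, before.links[["prey", "consumer"]].to_numpy()))
    a = set(map(tuple, after.links[["prey", "consumer"]].to_numpy()))
    assert b <= a


def _meta_for(samples):
    rows = []
    for i, s in enumerate(samples):
        cond = i % 2
        rows.append({"sample_id": s, "station": f"st{cond}", "area": "A",
                     "defoliation": cond})
    return SampleMetadata(pd.DataFrame(rows))


def test_class_proportion_change_identical_webs():
    w = LocalWeb(sample_id="s0", resolution="class",
                 node_weights=pd.Series({"X": 0.5, "Y": 0.5}),
                 links=pd.DataFrame([{"prey": "X", "consumer": "Y", "weight": 1.0}]))
    webs = []
    for s in ("s0", "s1", "s2", "s3"):
        webs.append(LocalWeb(sample_id=s, resolution="class",
                             node_weights=w.node_weights.copy(),
                             links=w.links.copy()))
    nodes, links = class_proportion_change(webs, _meta_for(["s0", "s1", "s2", "s3"]))
    assert (nodes["change"] == 0).all()
    assert (links["change"] == 0).all()


def test_class_proportion_change_single_pair():
    w0 = LocalWeb(sample_id="s0", resolution="class",
                  node_weights=pd.Series({"X": 0.8, "Y": 0.2}),
                  links=pd.DataFrame(columns=["prey", "consumer", "weight"]))
    w1 = LocalWeb(sample_id="s1", resolution="class",
                  node_weights=pd.Series({"X": 0.3, "Y": 0.7}),
                  links=pd.DataFrame(columns=["prey", "consumer", "weight"]))
    nodes, _ = class_proportion_change([w0, w1], _meta_for(["s0", "s1"]))
    assert nodes.at["X", "change"] == pytest.approx(-0.5)
    assert nodes.at["Y", "change"] == pytest.approx(0.5)
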