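import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilfoodweb import (HierarchicalFitSpec, estimate_lambda,
                         fit_defoliation_effect, mdmr_test, yeo_johnson)
from soilfoodweb.errors import ValidationError
from soilfoodweb.io import SampleMetadata
from soilfoodweb.simulate import SimulationConfig, simulate_design
from soilfoodweb.stats import effect_table, fit_defoliation_effects_batched

REDUCED = dict(iterations=1500, chains=4)


@pytest.fixture(scope="module")
def design():
    return simulate_design(SimulationConfig())


def _design_vectors(meta):
    tab = meta.table.set_index("sample_id")
    return (tab["defoliation"].to_numpy(float),
            pd.Categorical(tab["station"]).codes,
            pd.Categorical(tab["area"]).codes)


# ---------------------------------------------------------------------------
# Yeo-Johnson
# ---------------------------------------------------------------------------


def test_yeo_johnson_branches():
    x = np.array([-2.0, -0.5, 0.0, 0.7, 3.0])
    assert np.allclose(yeo_johnson(x, 1.0), x)  # identity branch
    assert yeo_johnson(np.e - 1.0, 0.0) == pytest.approx(1.0)
    assert yeo_johnson(-0.5, 2.0) == pytest.approx(-np.log(1.5))


@settings(derandomize=True, database=None, max_examples=100)
@given(st.floats(min_value=-3.0, max_value=5.0))
def test_yeo_johnson_strictly_monotone(lmbda):
    grid = np.linspace(-4.0, 4.0, 41)
    out = yeo_johnson(grid, lmbda)
    assert (np.diff(out) > 0).all()


def test_estimate_lambda_recovery():
    rng = np.random.default_rng(5)
    normal = rng.normal(2.0, 1.0, 1000)
    assert abs(estimate_lambda(normal).lmbda - 1.0) < 0.2
    lognormal = np.exp(rng.normal(0.0, 0.5, 1000)) - 1.0
    assert abs(estimate_lambda(lognormal).lmbda - 0.0) < 0.2


def test_estimate_lambda_flags_boundary_and_rejects_constant():
    rng = np.random.default_rng(6)
    skewed = np.exp(rng.normal(0.0, 0.5, 500)) - 1.0  # true lambda near 0
    est = estimate_lambda(skewed, window=(0.9, 1.1))
    assert est.boundary
    with pytest.raises(ValidationError, match="distinct"):
        estimate_lambda(np.full(10, 3.0))


# ---------------------------------------------------------------------------
# Hierarchical defoliation model
# ---------------------------------------------------------------------------


def test_fit_recovers_positive_effect(design):
    d, s, a = _design_vectors(design)
    rng = np.random.default_rng(2)
    y = pd.Series(0.2 + 0.5 * d + rng.normal(0, 0.05, len(d)),
                  index=design.samples)
    est = fit_defoliation_effect(y, design,
                                 HierarchicalFitSpec(seed=3, **REDUCED))
    assert est.effect > 0
    assert est.ci_low > 0  # interval excludes zero
    assert est.ci_low <= est.effect <= est.ci_high
    assert 0.3 < est.effect < 0.7


def test_constant_response_gives_zero_effect(design):
    y = pd.Series(0.3, index=design.samples)
    est = fit_defoliation_effect(y, design,
                                 HierarchicalFitSpec(seed=1, iterations=400,
                                                     chains=2))
    assert est.effect == 0.0
    assert est.ci_low <= 0.0 <= est.ci_high


def test_shift_equivariance(design):
    d, s, a = _design_vectors(design)
    rng = np.random.default_rng(4)
    y = 0.1 + 0.3 * d + rng.normal(0, 0.1, len(d))
    spec = HierarchicalFitSpec(seed=9, **REDUCED)
    e1 = fit_defoliation_effect(pd.Series(y, index=design.samples), design, spec)
    e2 = fit_defoliation_effect(pd.Series(y + 5.0, index=design.samples),
                                design, spec)
    assert e2.effect == pytest.approx(e1.effect, abs=1e-9)
    assert e2.ci_low == pytest.approx(e1.ci_low, abs=1e-9)


def test_bootstrap_path(design):
    d, _, _ = _design_vectors(design)
    rng = np.random.default_rng(8)
    y = pd.Series(0.2 + 0.5 * d + rng.normal(0, 0.05, len(d)),
                  index=design.samples)
    est = fit_defoliation_effect(
        y, design, HierarchicalFitSpec(method="bootstrap", seed=3))
    assert est.ci_low > 0 and 0.3 < est.effect < 0.7
    assert np.isnan(est.rhat)


def test_degenerate_design_rejected():
    cfg = SimulationConfig(n_areas=1, stations_per_area_per_condition=1,
                           cores_per_station=5)
    meta = simulate_design(cfg)
    y = pd.Series(np.arange(10, dtype=float), index=meta.samples)
    with pytest.raises(ValidationError, match="degenerate"):
        fit_defoliation_effect(y, meta, HierarchicalFitSpec(seed=1))


def test_effect_table_schema(design):
    d, _, _ = _design_vectors(design)
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(
        {s: v for s, v in zip(design.samples,
                              (0.1 + 0.4 * d + rng.normal(0, 0.1, (3, len(d)))).T)},
        index=["g1", "g2", "g3"])
    out = effect_table(mat, design,
                       HierarchicalFitSpec(seed=5, iterations=600, chains=2))
    assert list(out["group_id"]) == ["g1", "g2", "g3"]
    assert ((out["ci_low"] <= out["effect"]) & (out["effect"] <= out["ci_high"])).all()


# ---------------------------------------------------------------------------
# MDMR
# ---------------------------------------------------------------------------


def test_mdmr_rejects_asymmetric(design):
    n = len(design.samples)
    D = np.zeros((n, n)); D[0, 1] = 1.0
    with pytest.raises(ValidationError, match="symmetric"):
        mdmr_test(D, design)


def test_mdmr_perfect_separation_minimum_p(design):
    """Two perfectly condition-separated blocks reach the smallest p the
    restricted permutation space allows: only the global label flip ties
    the observed statistic, so p = 2 / 36 under exhaustive enumeration."""
    d = design.condition().to_numpy(float)
    D = np.abs(d[:, None] - d[None, :])
    res = mdmr_test(D, design, permutations="exhaustive")
    assert res.n_permutations == 35
    assert res.p_value == pytest.approx(2.0 / 36.0)
    assert (res.perm_stats <= res.statistic + 1e-9).all()


def test_mdmr_sample_order_invariance(design):
    rng = np.random.default_rng(10)
    X = rng.normal(size=(len(design.samples), 3))
    from scipy.spatial.distance import pdist, squareform
    D = pd.DataFrame(squareform(pdist(X)), index=design.samples,
                     columns=design.samples)
    r1 = mdmr_test(D, design, n_permutations=99, seed=0)
    perm = rng.permutation(design.samples)
    r2 = mdmr_test(D.loc[perm, perm], design, n_permutations=99, seed=0)
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_mdmr_detects_structure(design):
    """Condition-driven structure plus noise yields a small p-value."""
    rng = np.random.default_rng(12)
    d = design.condition().to_numpy(float)
    X = np.column_stack([d * 2.0 + rng.normal(0, 0.3, len(d)),
                         rng.normal(0, 0.3, len(d))])
    from scipy.spatial.distance import pdist, squareform
    D = squareform(pdist(X))
    res = mdmr_test(D, design, n_permutations=199, seed=1)
    assert res.p_value <= 0.05
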