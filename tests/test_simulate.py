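import numpy as np
import pandas as pd
import pytest

from soilfoodweb import (assign_trophic_groups, group_relative_abundance,
                         hill_diversity_matrix)
from soilfoodweb.errors import ValidationError
from soilfoodweb.simulate import (SimulationConfig, default_group_config,
                                  expected_group_shares, simulate_design,
                                  simulate_motu_table)


def test_design_defaults():
    meta = simulate_design(SimulationConfig())
    tab = meta.table
    assert tab["station"].nunique() == 8
    assert len(tab) == 120
    per_station = tab.groupby("station").size()
    assert (per_station == 15).all()
    st = meta.stations()
    assert st.groupby(["area", "defoliation"]).size().eq(2).all()


def test_design_small_arithmetic():
    cfg = SimulationConfig(n_areas=1, stations_per_area_per_condition=1,
                           cores_per_station=2)
    assert len(simulate_design(cfg).table) == 4


def test_determinism_bit_identical():
    cfg = SimulationConfig(seed=123)
    t1, g1, m1 = simulate_motu_table(cfg)
    t2, g2, m2 = simulate_motu_table(SimulationConfig(seed=123))
    assert t1 == t2
    pd.testing.assert_frame_equal(m1.table, m2.table)
    pd.testing.assert_frame_equal(g1.station_intercepts, g2.station_intercepts)
    t3, _, _ = simulate_motu_table(SimulationConfig(seed=124))
    assert not t1.counts.equals(t3.counts)


def test_counts_are_nonnegative_integers(sim_run):
    table, _, _ = sim_run
    arr = table.counts.to_numpy()
    assert arr.dtype.kind == "i"
    assert (arr >= 0).all()
    assert (arr.sum(axis=0) > 0).all()


def test_unknown_group_rejected(scheme):
    groups = default_group_config().copy()
    groups = groups.rename(index={groups.index[0]: "martian_microbes"})
    with pytest.raises(ValidationError, match="martian_microbes"):
        simulate_motu_table(SimulationConfig(groups=groups), scheme=scheme)


def test_retained_samples_dropout():
    cfg = SimulationConfig(seed=5, retained_samples=86)
    table, _, meta = simulate_motu_table(cfg)
    assert len(table.samples) == 86
    assert meta.samples == table.samples


def test_null_case_no_condition_difference(scheme):
    """With all beta=0, delta=1 the mean double-transformed abundance per
    group differs between conditions by < 3 Monte-Carlo standard errors."""
    cfg = SimulationConfig(groups=default_group_config(preset="null"),
                           cores_per_station=125, seed=42)  # 1000 samples
    table, _, meta = simulate_motu_table(cfg, scheme=scheme)
    rel = group_relative_abundance(assign_trophic_groups(table, scheme)).values
    # station/area intercepts correlate cores within a station, so the
    # Monte-Carlo SE of the condition contrast is taken between stations
    stations = meta.table.set_index("sample_id")["station"].reindex(rel.columns)
    st_means = rel.T.groupby(stations).mean().T  # groups x stations
    st_cond = meta.stations().set_index("station")["defoliation"]
    a = st_means.loc[:, st_cond == 0]
    b = st_means.loc[:, st_cond == 1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(a.var(axis=1) / a.shape[1] + b.var(axis=1) / b.shape[1])
    frac_ok = (diff.abs() < 3 * se.replace(0, np.inf)).mean()
    assert frac_ok >= 0.9


def test_directional_effects_on_read_share(scheme):
    groups = default_group_config(preset="null").copy()
    groups.loc["ectomycorrhizal_fungi", "beta"] = -1.0
    groups.loc["arbuscular_mycorrhizal_fungi", "beta"] = 1.0
    cfg = SimulationConfig(groups=groups, seed=11)
    table, _, meta = simulate_motu_table(cfg, scheme=scheme)
    assigned = assign_trophic_groups(table, scheme)
    reads = assigned.reads_by_group()
    share = reads / reads.sum(axis=0)
    cond = meta.condition().reindex(share.columns)
    ecm = share.loc["ectomycorrhizal_fungi"]
    amf = share.loc["arbuscular_mycorrhizal_fungi"]
    assert ecm[cond == 1].mean() < ecm[cond == 0].mean()
    assert amf[cond == 1].mean() > amf[cond == 0].mean()


def test_delta_raises_hill_diversity(scheme):
    """delta=2 for one group makes its per-sample Hill-Shannon MOTU
    diversity strictly higher under defoliation (paired simulation)."""
    groups = default_group_config(preset="null").copy()
    groups.loc["saprotrophic_fungi", "delta"] = 2.0
    cfg = SimulationConfig(groups=groups, cores_per_station=63, seed=17)  # ~500/cond
    table, _, meta = simulate_motu_table(cfg, scheme=scheme)
    hill = hill_diversity_matrix(assign_trophic_groups(table, scheme)).values
    cond = meta.condition().reindex(hill.columns)
    row = hill.loc["saprotrophic_fungi"]
    assert row[cond == 1].mean() > row[cond == 0].mean()


def test_expected_share_monotone_in_beta():
    """Increasing beta_g strictly increases the expected defoliated share
    (common-random-number grid)."""
    grid = np.linspace(-1.0, 2.0, 7)
    shares = []
    for b in grid:
        groups = default_group_config(preset="null").copy()
        groups.loc["collembola", "beta"] = b
        shares.append(expected_group_shares(
            SimulationConfig(groups=groups), defoliated=True)["collembola"])
    assert all(b > a for a, b in zip(shares, shares[1:]))
    # undamaged shares are untouched by beta
    base = expected_group_shares(SimulationConfig(), defoliated=False)
    assert base["collembola"] == pytest.approx(
        expected_group_shares(SimulationConfig(groups=groups),
                              defoliated=False)["collembola"])


def test_config_validation():
    groups = default_group_config().copy()
    groups.loc[groups.index[0], "delta"] = 0.0
    with pytest.raises(ValidationError, match="delta"):
        SimulationConfig(groups=groups)
    with pytest.raises(ValidationError, match="positive"):
        SimulationConfig(cores_per_station=0)
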