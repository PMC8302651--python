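import numpy as np
import pandas as pd
import pytest

from soilfoodweb import (assign_trophic_groups, build_metaweb, default_scheme,
                         group_relative_abundance)
from soilfoodweb.localweb import LocalWeb
from soilfoodweb.simulate import (SimulationConfig, default_group_config,
                                  simulate_motu_table)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def metaweb(scheme):
    return build_metaweb(scheme)


@pytest.fixture(scope="session")
def sim_run(scheme):
    """One paper_signs simulation at the study size (86 retained samples)."""
    cfg = SimulationConfig(groups=default_group_config(preset="paper_signs"),
                           seed=3, retained_samples=86)
    return simulate_motu_table(cfg, scheme=scheme)


@pytest.fixture(scope="session")
def assigned(sim_run, scheme):
    table, _, _ = sim_run
    return assign_trophic_groups(table, scheme)


@pytest.fixture(scope="session")
def rel_abund(assigned):
    return group_relative_abundance(assigned)


def random_group_web(rng, max_groups=12, max_classes=4):
    """A random small group-level local web plus its class map.

    Used as raw material for brute-force oracle comparisons.
    """
    n = int(rng.integers(2, max_groups + 1))
    k = int(rng.integers(1, max_classes + 1))
    groups = [f"g{i}" for i in range(n)]
    classes = {g: f"c{rng.integers(k)}" for g in groups}
    p = rng.uniform(0.05, 1.0, n)
    adj = (rng.random((n, n)) < 0.4).astype(float)
    np.fill_diagonal(adj, 0.0)
    links = [{"prey": groups[i], "consumer": groups[j], "weight": 1.0}
             for i in range(n) for j in range(n) if adj[i, j]]
    web = LocalWeb(sample_id=f"s{rng.integers(1 << 30)}", resolution="group",
                   node_weights=pd.Series(p, index=groups),
                   links=pd.DataFrame(links, columns=["prey", "consumer", "weight"]))
    return web, classes, adj


def scheme_from_classmap(classes):
    """Minimal TrophicScheme carrying only a group->class map."""
    from soilfoodweb.io import TrophicScheme
    groups = pd.DataFrame({
        "class_id": pd.Series(classes),
        "size_rank": 1, "organism_scale": "micro",
        "endoparasite": False, "cross_scale_feeder": False,
        "size_exception": False, "resource_links": "", "prey": "", "avoid": "",
    })
    groups.index.name = "group"
    lookup = pd.DataFrame(columns=["clade", "rank", "guild", "group"])
    return TrophicScheme(groups=groups, lookup=lookup)
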