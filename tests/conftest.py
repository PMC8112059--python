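import numpy as np
import pandas as pd
import pytest

from arena.config import SimulationConfig
from arena import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_clinical=300, n_are_only=40, n_positive_ctrl=20,
                            n_tss=60, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One simulated dataset shared across read-only tests."""
    regions, truth = sim.simulate_regions(small_config)
    counts, roles = sim.simulate_starr_counts(regions, truth, small_config)
    tss = sim.simulate_tss(small_config)
    loops = sim.simulate_interactions(regions, truth, tss, small_config)
    raw, ctrl = sim.simulate_occupancy(regions, truth, small_config)
    co_etoh, co_dht = sim.simulate_coaccessibility(regions, truth, small_config)
    return {"config": small_config, "regions": regions, "truth": truth,
            "counts": counts, "roles": roles, "tss": tss, "loops": loops,
            "occ_raw": raw, "occ_ctrl": ctrl,
            "co_etoh": co_etoh, "co_dht": co_dht}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_labeled_graph(rng, n_max=8, classes=("a", "b", "c")):
    """Small random labeled graph (possibly with self-loops) for oracles."""
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    labels = rng.choice(classes, size=n)
    for i in range(n):
        g.add_node(f"n{i}", node_class=str(labels[i]))
    p_edge = rng.uniform(0.2, 0.7)
    for i in range(n):
        for j in range(i, n):
            if rng.random() < (p_edge if i != j else p_edge / 4):
                g.add_edge(f"n{i}", f"n{j}")
    return g
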