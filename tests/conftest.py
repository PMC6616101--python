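import numpy as np
import pytest

from polyasig.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_result():
    """A mid-sized synthetic dataset shared across test modules."""
    return simulate(SimConfig(n_genes=150, seed=42))


@pytest.fixture(scope="session")
def sim_clusters(sim_result):
    from polyasig.sites import cluster_cleavage_events

    return cluster_cleavage_events(sim_result.events)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
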