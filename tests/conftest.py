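import numpy as np
import pytest

from hairwave.periodicity import build_frequency_grid
from hairwave.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic dataset shared across tests (seed 0)."""
    cfg = SimulationConfig(seed=0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """Reduced probe counts for faster end-to-end stages."""
    cfg = SimulationConfig(
        seed=3,
        n_probes_cluster1=60,
        n_probes_cluster2=100,
        n_noise_probes=120,
        n_feedback_probes=8,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_basis(default_sim):
    ds, _ = default_sim
    return build_frequency_grid(ds.merged_day)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
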