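import numpy as np
import pytest

from twinjoint import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dense_config() -> SimulationConfig:
    """Reference dense-grid, error-free study conditions."""
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def sparse_config() -> SimulationConfig:
    """Sparse-grid conditions with moderate measurement error."""
    return SimulationConfig(seed=42, grid_scheme="sparse", grid_max_k=3, sigma_e=0.1)


@pytest.fixture(scope="session")
def small_dense_dataset():
    """A small dense-grid dataset shared across fast tests."""
    return simulate_dataset(SimulationConfig(n_pairs=250, seed=5))


@pytest.fixture(scope="session")
def small_sparse_dataset():
    """A small sparse-grid dataset with measurement error."""
    return simulate_dataset(
        SimulationConfig(n_pairs=250, seed=5, grid_scheme="sparse", grid_max_k=3, sigma_e=0.1)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
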