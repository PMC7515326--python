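import numpy as np
import pytest

from plzcmeg import SimulationConfig, make_grid, simulate_cohort


@pytest.fixture(scope="session")
def small_grid():
    """27-source 3x3x3 grid with 4 contiguous regions."""
    return make_grid((3, 3, 3), 10.0, 4, seed=0)


@pytest.fixture(scope="session")
def flat_grid():
    """5x5x3 grid used for clustering oracle checks."""
    return make_grid((5, 5, 3), 10.0, 8, seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast cohort with a planted high-beta effect (8 subjects/group)."""
    cfg = SimulationConfig(n_per_group=8, n_epochs_mean=4, n_epochs_sd=1,
                           n_epochs_min=3, n_epochs_max=6, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
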