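import numpy as np
import pytest

from turnoverkit.synthetic import (
    SimulationConfig,
    simulate_abundance_matrix,
    simulate_labeling_cohort,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Study-design config at a size small enough for unit tests."""
    return SimulationConfig(n_proteins=30, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_labeling_cohort(small_config, seed=1)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimulationConfig(n_proteins=15, envelope_cv=0.0, missing_rate=0.0, seed=3)
    return simulate_labeling_cohort(cfg, seed=3)


@pytest.fixture(scope="session")
def abundance_default():
    cfg = SimulationConfig(n_proteins=300, seed=11)
    return simulate_abundance_matrix(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
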