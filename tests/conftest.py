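import numpy as np
import pytest

from driftindex import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config():
    """A fast community, small enough for exhaustive checks."""
    return SimulationConfig(J=60, S=6, n_years=25, n_replicates=20, seed=101)


@pytest.fixture(scope="session")
def small_ensemble(small_config):
    return [simulate(small_config, r) for r in range(small_config.n_replicates)]


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
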