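import pytest

from recipz import SimulationConfig


@pytest.fixture
def sim_config() -> SimulationConfig:
    """Full-size study conditions: N = 20,000 draws, 10 replicate seeds."""
    return SimulationConfig()


@pytest.fixture
def small_config() -> SimulationConfig:
    """Reduced Monte Carlo for unit tests where precision is not at stake."""
    return SimulationConfig(n=4_000, seed=7, replicates=3)
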