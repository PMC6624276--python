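import pytest

from fateinfo import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def strong_experiment():
    """Default simulation: strong continuous negative expression-death link."""
    return simulate_experiment(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_experiment():
    """Matched simulation with death independent of fluorescence."""
    return simulate_experiment(SimulationConfig(link_shape="none", seed=7))
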