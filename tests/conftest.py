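import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from motudelim import easy_config, deep_config, simulate_assemblage

#: the fixed seed used for all simulation-based regression checks
SIM_SEED = 42


@pytest.fixture(scope="session")
def easy_assemblage():
    """Cleanly separated regime: every method should recover the truth."""
    return simulate_assemblage(easy_config(), SIM_SEED)


@pytest.fixture(scope="session")
def deep_assemblage():
    """Half the species carry a deep basal split (hard regime)."""
    return simulate_assemblage(deep_config(), SIM_SEED)


@pytest.fixture(scope="session")
def default_assemblage():
    from motudelim import SimulationConfig

    return simulate_assemblage(SimulationConfig(), SIM_SEED)
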