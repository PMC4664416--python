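import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prevproj import SyntheticSpec, generate_country

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def country():
    """The default synthetic country (deterministic; shared across tests)."""
    return generate_country(SyntheticSpec())


@pytest.fixture(scope="session")
def short_country():
    """A shorter-horizon country for solver and toy scenario tests."""
    return generate_country(SyntheticSpec(horizon_end=2035))


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
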