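import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from patchforage import PatchEnvironment

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env():
    """Reference patch: rho=2, tau=5, alpha=1, T_I=5."""
    return PatchEnvironment(rho=2.0, tau=5.0, alpha=1.0, travel_time=5.0)


@pytest.fixture(scope="session")
def rich_env():
    """High-food patch (rho=6), same costs and timescales."""
    return PatchEnvironment(rho=6.0, tau=5.0, alpha=1.0, travel_time=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
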