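import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneesim import generate_synthetic_knee
from kneesim.simulator import SquatProtocol, equilibrium_settle, run_squat

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    """Generated (unsettled) default knee; treat as read-only."""
    return generate_synthetic_knee()


@pytest.fixture(scope="session")
def settled_model():
    """Settled default knee; tests must work on .copy()."""
    model = generate_synthetic_knee()
    equilibrium_settle(model)
    return model


@pytest.fixture(scope="session")
def short_protocol():
    """Reduced squat discretization for unit tests (same timestep as default)."""
    return SquatProtocol(cycle_samples=31)


@pytest.fixture(scope="session")
def short_trace(settled_model, short_protocol):
    return run_squat(settled_model.copy(), short_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
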