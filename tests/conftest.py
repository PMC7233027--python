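import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gonogo import taskenv  # noqa: E402
from gonogo.models import get_model  # noqa: E402

#: group-mean parameters of the active-inference empirical priors
AI_MEANS = dict(
    alpha=1.627, c_tau=5.785, f=0.593,
    p_W=0.5163, p_go_W=0.5211, p_nogo_AL=0.5063,
)

RL7_VALUES = dict(
    rho_win=2.0, rho_loss=2.0, epsilon=0.15, xi=0.85, b=0.3, pi_c=0.3
)


@pytest.fixture(scope="session")
def schedule144():
    return taskenv.make_schedule(36, seed=123)


@pytest.fixture
def ai_means():
    return dict(AI_MEANS)


@pytest.fixture
def rl7_values():
    return dict(RL7_VALUES)


@pytest.fixture(scope="session")
def rl7_session(schedule144):
    """A reproducible session simulated from RL Model 7."""
    model = get_model("rl7")
    return model.simulate(schedule144, RL7_VALUES, np.random.default_rng(7))


@pytest.fixture(scope="session")
def ai_session(schedule144):
    """A reproducible session simulated from the active-inference agent."""
    model = get_model("ai")
    return model.simulate(schedule144, AI_MEANS, np.random.default_rng(8))
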