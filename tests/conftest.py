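import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rept import PsiConfig, SimulatedObserver, WeibullParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def small_psi_config() -> PsiConfig:
    """A deliberately tiny grid so brute-force oracles stay cheap."""
    return PsiConfig(
        alpha_values=np.linspace(40.0, 80.0, 5),
        beta_values=np.geomspace(2.0, 16.0, 5),
        x_values=np.arange(30.0, 91.0, 10.0),
        max_trials=10,
    )


@pytest.fixture
def typical_observer() -> SimulatedObserver:
    """A mid-range phosphene detector used across integration tests."""
    return SimulatedObserver(WeibullParams(60.0, 10.0, 0.0, 0.04), seed=12345)


def step_responder(threshold: float):
    """Deterministic observer: sees the phosphene iff x >= threshold."""

    def respond(x):
        return int(x >= threshold)

    return respond
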