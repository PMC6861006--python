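import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vesipool.kinetics import RecoveryModel
from vesipool.sim import make_schedule

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standard_model():
    """Typical wild-type-like recovery: 70% mobile, 40% fast component."""
    return RecoveryModel(plateau=0.7, fast_fraction=0.4, half_fast=60.0, half_slow=1200.0)


@pytest.fixture
def schedule():
    return make_schedule()
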