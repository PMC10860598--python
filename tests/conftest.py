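import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dsriem.basis import ChannelBasis
from dsriem.design import build_design

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def loc_basis():
    return ChannelBasis.location()


@pytest.fixture(scope="session")
def ori_basis():
    return ChannelBasis.orientation()


@pytest.fixture(scope="session")
def full_design():
    """The study-scale schedule: 324 trials in 27 runs."""
    return build_design(seed=1)


@pytest.fixture(scope="session")
def small_design():
    """One repetition per trial type (108 trials, 9 runs), on-grid locations."""
    return build_design(seed=3, reps=1, jitter_max=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
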