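import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import motorwheel as mw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ascending():
    return mw.SpeedProfile.ascending()


@pytest.fixture(scope="session")
def descending():
    return mw.SpeedProfile.descending()


@pytest.fixture(scope="session")
def short_profile():
    """Miniature profile (10-s blocks) for fast peri-transition tests."""
    return mw.SpeedProfile((0.0, 15.0, 30.0, 45.0, 60.0, 0.0), 40.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
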