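import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from arcpipe.io import events_by_kind
from arcpipe.synth import make_session

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def feeding_session():
    """One full synthetic feeding session under the default study
    conditions (10-min baseline, 5-min cue period, 45-min feeding,
    100-train tagging block)."""
    return make_session(seed=11)


@pytest.fixture(scope="session")
def session_events(feeding_session):
    return events_by_kind(feeding_session.events)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
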