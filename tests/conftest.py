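import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ipmap import (
    BodyModel,
    ImmersionModel,
    SimulationScript,
    make_cohort,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: A short version of the study protocol (supine, high sitting, supine,
#: lateral) used where the full 60 s segments would be needless work.
SHORT_SCRIPT = SimulationScript(
    segments=(
        ("supine", 20.0),
        ("high_sitting", 20.0),
        ("supine", 20.0),
        ("lateral_right", 20.0),
    ),
    transition_duration=5.0,
)

#: Class-balanced protocol: one segment per posture, equal durations.
BALANCED_SCRIPT = SimulationScript(
    segments=(
        ("supine", 20.0),
        ("high_sitting", 20.0),
        ("lateral_right", 20.0),
    ),
    transition_duration=5.0,
)


@pytest.fixture(scope="session")
def body():
    return BodyModel.default()


@pytest.fixture(scope="session")
def foam():
    return ImmersionModel.foam()


@pytest.fixture(scope="session")
def air():
    return ImmersionModel.air()


@pytest.fixture(scope="session")
def small_cohort():
    """Three subjects on foam, short protocol: enough structure for the
    event and classification pipelines at test scale."""
    return make_cohort(3, regime="foam", seed=11, script=SHORT_SCRIPT)


@pytest.fixture(scope="session")
def balanced_cohort():
    """Five subjects, one segment per posture - balanced class counts."""
    return make_cohort(5, regime="foam", seed=13, script=BALANCED_SCRIPT)
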