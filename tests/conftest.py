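import numpy as np
import pytest

from pdmotion.recordings import SensorPlacement
from pdmotion.synth import ProtocolScript, SubjectProfile, generate_cohort, generate_session

GAIT_SENSORS = (
    SensorPlacement.LEFT_ANKLE,
    SensorPlacement.RIGHT_ANKLE,
    SensorPlacement.CHEST,
)
HAND_SENSORS = (SensorPlacement.LEFT_WRIST, SensorPlacement.RIGHT_WRIST)


@pytest.fixture(scope="session")
def short_script() -> ProtocolScript:
    """One pass of the default activity sequence (70 s)."""
    return ProtocolScript(repetitions=1)


@pytest.fixture(scope="session")
def session_a(short_script):
    return generate_session(SubjectProfile(seed=7), short_script, subject_id="S_A")


@pytest.fixture(scope="session")
def cohort6(short_script):
    """Six-subject cohort shared by the evaluation tests."""
    return generate_cohort(6, base_seed=11, script=short_script)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
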