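import pytest

from eegresp import RecordingSpec, SubjectProfile, generate_cohort, generate_recording


@pytest.fixture(scope="session")
def short_spec():
    """10 s single-condition recordings with all artifact families enabled."""
    return RecordingSpec(duration=10.0, conditions=("eyes_closed",))


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile(subject_id="S001", sex="female", bdi_pre=32, bdi_post=10,
                          true_class_effect=0.0)


@pytest.fixture(scope="session")
def short_recording(subject, short_spec):
    return generate_recording(subject, short_spec, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects (2 per sex, half responders), 4 s recordings, both sessions
    and conditions — just enough structure for dataset-assembly tests."""
    spec = RecordingSpec(duration=4.0)
    return generate_cohort(2, 2, {"female": 0.5, "male": 0.5}, spec, seed=7,
                           class_effect=1.0, session_effect=0.5)
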