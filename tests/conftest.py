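import numpy as np
import pytest

from semgpipe.synthetic import (ProtocolEvent, ProtocolSchedule, SubjectProfile,
                                make_schedule, simulate_recording)


@pytest.fixture(scope="session")
def senior_profile():
    return SubjectProfile(subject_id="S01", group="senior", max_force=3.1,
                          max_torque=5.9, separability=0.6, noise_floor=0.065)


@pytest.fixture(scope="session")
def young_profile():
    return SubjectProfile(subject_id="Y01", group="young", max_force=4.2,
                          max_torque=3.4, separability=0.9, noise_floor=0.04)


@pytest.fixture(scope="session")
def short_schedule():
    """A compact two-event schedule (grasp then ulnar deviation)."""
    return ProtocolSchedule(name="C", arm_position="pronation", events=(
        ProtocolEvent(class_id=2, start_s=1.0, duration_s=2.0, envelope_level=0.5),
        ProtocolEvent(class_id=4, start_s=4.0, duration_s=2.0, envelope_level=0.5),
    ))


@pytest.fixture(scope="session")
def short_recording(short_schedule, young_profile):
    return simulate_recording(short_schedule, young_profile, seed=11)


@pytest.fixture(scope="session")
def protocol_d_recording(senior_profile):
    return simulate_recording(make_schedule("D"), senior_profile, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
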