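import numpy as np
import pytest

from strikeslide.design import make_design
from strikeslide.synth import ParticipantProfile, simulate_participant_session


@pytest.fixture(scope="session")
def noiseless_session():
    """Four blocks x 3 trials with full kinematics and no noise of any kind."""
    profile = ParticipantProfile(motor_noise_sd=0.0, marker_noise_sd=0.0)
    design = make_design(1, 3)
    return simulate_participant_session(profile, design, seed=42)


@pytest.fixture(scope="session")
def noisy_session():
    """Full kinematics with motor noise and 0.5 mm marker noise."""
    profile = ParticipantProfile(motor_noise_sd=0.05, marker_noise_sd=0.0005)
    design = make_design(2, 3)
    return simulate_participant_session(profile, design, seed=43)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
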