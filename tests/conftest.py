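import numpy as np
import pytest

from threatphys.design import Phase, generate_trial_sequence
from threatphys.synthgen import SimConfig


@pytest.fixture(scope="session")
def quiet_config() -> SimConfig:
    """Noise- and artifact-free study conditions (forward-model identities)."""
    return SimConfig(seed=11, noise=dict(emg=0.0, sc=0.0, pupil=0.0, ecg=0.0),
                     artifact_rates=dict(pupil_blink_per_min=0.0,
                                         sc_artifact_per_min=0.0))


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def acquisition_seq():
    return generate_trial_sequence(Phase.ACQUISITION, 17)


@pytest.fixture(scope="session")
def retention_seq():
    return generate_trial_sequence(Phase.RETENTION, 17)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
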