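import numpy as np
import pytest

from mspli import EEGRecording
from mspli.synthetic import CouplingSpec, SimConfig, generate_subject_eeg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sinusoid_rec():
    """Two 9 Hz sinusoids, the second lagging by pi/3, plus a zero channel."""
    rate = 250.0
    t = np.arange(int(rate * 20)) / rate
    data = np.vstack(
        [
            np.sin(2 * np.pi * 9.0 * t),
            np.sin(2 * np.pi * 9.0 * t - np.pi / 3),
            np.zeros_like(t),
        ]
    )
    return EEGRecording(data=data, rate=rate, labels=["a", "b", "zero"])


@pytest.fixture(scope="session")
def pure_lag_config():
    """One coupled pair at strength 1, lag pi/4, no microstate component, no noise."""
    return SimConfig(
        n_subjects=4,
        n_channels=8,
        duration=60.0,
        noise_sd=0.0,
        ms_amplitude=0.0,
        coupling_spec=(CouplingSpec((0, 1), "alpha2", np.pi / 4, 1.0),),
        channel_labels=tuple(f"c{i}" for i in range(8)),
        seed=11,
    )


@pytest.fixture(scope="session")
def pure_lag_recording(pure_lag_config):
    rec, truth = generate_subject_eeg(pure_lag_config, 0, 26.0)
    return rec, truth


@pytest.fixture(scope="session")
def microstate_recording():
    """Default 4-template simulation at low noise, with ground truth."""
    cfg = SimConfig(duration=120.0, noise_sd=0.05, seed=3)
    rec, truth = generate_subject_eeg(cfg, 0, 26.0)
    return rec, truth
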