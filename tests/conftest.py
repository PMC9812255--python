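import numpy as np
import pytest

from stgcn_eeg.bands import ALPHA, FULL
from stgcn_eeg.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """Two-channel 10 Hz sinusoid recording at 100 Hz, 12 s."""
    t = np.arange(1200) / 100.0
    x = np.sin(2 * np.pi * 10 * t)
    return Recording(samples=np.stack([x, 0.5 * x]), fs=100.0,
                     channel_labels=["a", "b"], subject_id="s1",
                     group="HC-like", eye_state="EC")


@pytest.fixture
def noise_recording(rng):
    """23-channel white-noise recording at 100 Hz, 12 s."""
    from stgcn_eeg.montage import DEFAULT_BIPOLAR_LABELS

    return Recording(samples=rng.standard_normal((23, 1200)), fs=100.0,
                     channel_labels=list(DEFAULT_BIPOLAR_LABELS),
                     subject_id="s2", group="AD-like", eye_state="EO")


@pytest.fixture
def alpha_band():
    return ALPHA


@pytest.fixture
def full_band():
    return FULL
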