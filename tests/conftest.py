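import numpy as np
import pytest

from neuroedge.eeg_io import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng):
    """3-channel, 4 s at 250 Hz, ~10 uV noise."""
    data = rng.normal(0.0, 10.0, size=(3, 1000))
    return EEGRecording(
        data=data, fs=250.0, channel_labels=["Fp1", "Fp2", "Fpz"], session_id="fix1"
    )


@pytest.fixture
def sine_recording():
    """Single-channel 10 Hz unit sine at 256 Hz, 4 s."""
    fs = 256.0
    t = np.arange(int(4 * fs)) / fs
    return EEGRecording(
        data=np.sin(2 * np.pi * 10.0 * t)[None, :],
        fs=fs,
        channel_labels=["Cz"],
        session_id="sine",
    )
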