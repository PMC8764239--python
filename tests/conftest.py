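import numpy as np
import pytest

from tinnconn.types import Epoch, MultichannelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epoch(data, fs=250.0, labels=None, label=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return Epoch(data=data, sampling_rate=fs, channel_labels=labels, label=label)


def make_recording(data, fs=250.0, labels=None, group=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return MultichannelRecording(
        data=data, sampling_rate=fs, channel_labels=labels, group_label=group
    )


def sine(freq, fs, duration, phase=0.0, amp=1.0):
    t = np.arange(int(round(fs * duration))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def sine_wave():
    return sine


@pytest.fixture
def epoch_factory():
    return make_epoch


@pytest.fixture
def recording_factory():
    return make_recording
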