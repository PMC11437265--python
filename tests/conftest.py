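import numpy as np
import pytest

from neckvitals import TaskConfig


def tone(freq_hz: float, dur_s: float, fs: float, amp: float = 1.0, phase: float = 0.0):
    t = np.arange(int(round(dur_s * fs))) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


@pytest.fixture
def pulse_cfg():
    return TaskConfig.for_task("pulse")


@pytest.fixture
def resp_cfg():
    return TaskConfig.for_task("respiratory")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
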