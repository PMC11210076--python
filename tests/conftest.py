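import numpy as np
import pytest

from nvcoh.timefreq import make_log_grid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_grid():
    """Coarse log grid over 0.02-2 Hz for fast transform tests."""
    return make_log_grid(0.02, 2.0, 80)


def tone(freq, duration, fs, amplitude=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.cos(2 * np.pi * freq * t + phase)
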