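import numpy as np
import pytest

from cardiotouch.ecg import BeatSeries


def make_beats(r_times, systole_len=342.0, descent=80.0):
    """BeatSeries with T-end a fixed interval after each R-peak."""
    r = np.asarray(r_times, dtype=float)
    t_ends = r + systole_len
    t_peaks = t_ends - descent
    return BeatSeries(r, t_peaks, t_ends, np.ones(r.size, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_beats():
    """Six beats at a constant 800 ms IBI, systole 300 ms."""
    return make_beats(np.arange(6) * 800.0, systole_len=300.0)
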