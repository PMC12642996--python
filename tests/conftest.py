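import numpy as np
import pytest

from doctkit import TimeSeriesStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_stack(rng):
    """Small random stack with strictly positive intensities."""
    frames = rng.uniform(0.1, 2.0, size=(16, 6, 5))
    return TimeSeriesStack(frames, frame_rate_hz=50.0)


def make_stack(frames, rate=10.0, **kw):
    return TimeSeriesStack(np.asarray(frames, dtype=float), frame_rate_hz=rate, **kw)


def pixel_stack(series, rate=10.0):
    """A 1-pixel stack from a 1D time series (helper for hand-value tests)."""
    arr = np.asarray(series, dtype=float)[:, None, None]
    return TimeSeriesStack(arr, frame_rate_hz=rate)
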