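import numpy as np
import pandas as pd
import pytest

from temprhythm import EpochSeries


def _make_series(values, epoch_s=3600, start="2024-01-01", wear=None):
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start, periods=len(values), freq=f"{epoch_s}s")
    return EpochSeries(ts, values, wear)


@pytest.fixture
def make_series():
    """Factory: EpochSeries from values on a regular grid starting at midnight."""
    return _make_series


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def hourly_cosine(make_series):
    """Noiseless 24-h cosine (M=30, A=2, peak at midnight), hourly, 2 days."""
    t = np.arange(48)
    return make_series(30 + 2 * np.cos(2 * np.pi * t / 24), epoch_s=3600)
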