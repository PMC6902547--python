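import numpy as np
import pytest

from stridestab.gait_io import StrideTimeSeries
from stridestab.preprocess import DetrendedSeries


def make_series(values, subject_id="s1", group_label="control", foot="left", elapsed=None):
    return StrideTimeSeries(
        subject_id=subject_id,
        group_label=group_label,
        foot=foot,
        stride_times=np.asarray(values, dtype=float),
        elapsed_times=None if elapsed is None else np.asarray(elapsed, dtype=float),
        source="test",
    )


def make_detrended(values):
    """Wrap raw residual values without actually detrending (for AR unit tests)."""
    values = np.asarray(values, dtype=float)
    return DetrendedSeries(
        residuals=values, trend_intercept=0.0, trend_slope=0.0, n=values.size
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
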