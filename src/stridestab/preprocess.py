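"""Series cleaning and linear detrending.

The AR model is fitted to residuals of an ordinary least-squares line over
stride index (elapsed time is available as an alternative regressor).
Outlier removal exists for sensitivity analysis but is OFF by default, so the
default path is the literal procedure: detrend, then fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, ShortSeriesError
from .gait_io import MIN_SERIES_LENGTH, StrideTimeSeries

#: Scale factor making the median absolute deviation SD-consistent for
#: Gaussian data.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class DetrendedSeries:
    """Residuals of the linear-trend fit, ready for AR estimation."""

    residuals: np.ndarray
    trend_intercept: float
    trend_slope: float
    n: int
    outliers_removed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residuals", np.asarray(self.residuals, dtype=float))


def remove_outliers(
    series: StrideTimeSeries, k: float = 3.0, enabled: bool = False
) -> tuple[StrideTimeSeries, int]:
    """Drop strides more than ``k`` scaled MADs from the median.

    Disabled by default. A constant series is never altered (every deviation
    from the median is zero). Returns the (possibly filtered) series and the
    number of strides removed.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if not enabled:
        return series, 0
    x = series.stride_times
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    # zero MAD: threshold collapses to |x - med| <= 0, so a constant series
    # is untouched while strides off the (majority) median are dropped
    keep = np.abs(x - med) <= k * mad
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise DegenerateSeriesError(
            f"{series.subject_id}: outlier filter removed every stride"
        )
    if n_removed == 0:
        return series, 0
    filtered = StrideTimeSeries(
        subject_id=series.subject_id,
        group_label=series.group_label,
        foot=series.foot,
        stride_times=x[keep],
        elapsed_times=None
        if series.elapsed_times is None
        else series.elapsed_times[keep],
        source=series.source,
    )
    return filtered, n_removed


def detrend_linear(
    series: StrideTimeSeries,
    regressor: str = "index",
    outliers_removed: int = 0,
) -> DetrendedSeries:
    """Subtract the OLS line from the stride-time series.

    Parameters
    ----------
    series : StrideTimeSeries
        At least 30 strides.
    regressor : {"index", "elapsed"}
        Abscissa of the trend fit. ``index`` uses stride number 0..n-1 (the
        default convention for stride series); ``elapsed`` uses cumulative
        protocol time and requires ``series.elapsed_times``.
    outliers_removed : int
        Carried through for bookkeeping.
    """
    y = series.stride_times
    n = y.size
    if n < MIN_SERIES_LENGTH:
        raise ShortSeriesError(
            f"{series.subject_id}: {n} strides (< {MIN_SERIES_LENGTH}) — too short to detrend"
        )
    if regressor == "index":
        t = np.arange(n, dtype=float)
    elif regressor == "elapsed":
        if series.elapsed_times is None:
            raise ValueError("elapsed regressor requested but series has no elapsed_times")
        t = series.elapsed_times.astype(float)
    else:
        raise ValueError(f"unknown regressor {regressor!r}")

    slope, intercept = np.polyfit(t, y, 1)
    residuals = y - (intercept + slope * t)
    return DetrendedSeries(
        residuals=residuals,
        trend_intercept=float(intercept),
        trend_slope=float(slope),
        n=n,
        outliers_removed=outliers_removed,
    )


def preprocess_series(
    series: StrideTimeSeries,
    outliers_enabled: bool = False,
    outlier_k: float = 3.0,
    regressor: str = "index",
) -> DetrendedSeries:
    """Convenience: optional outlier filter, then linear detrend."""
    filtered, n_removed = remove_outliers(series, k=outlier_k, enabled=outliers_enabled)
    return detrend_linear(filtered, regressor=regressor, outliers_removed=n_removed)
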