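"""Cohort-level statistics.

Two-sample t-tests on the per-subject metrics, 95% coverage ellipses in the
coefficient plane, a distance-threshold classifier, and the per-group summary
table. Note the classifier is a reconstruction: the source analysis reports
accuracy/sensitivity/specificity without defining the procedure, so outputs
are labeled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AggregationError,
    ClassBalanceError,
    DegenerateGeometryError,
    ParameterError,
)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    df: float
    p_value: float
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class CoverageEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis
    coverage_target: float
    empirical_coverage: float


@dataclass(frozen=True)
class ClassificationReport:
    """Distance-threshold classifier metrics (declared reconstruction)."""

    threshold: float
    positive_label: str
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[TP, FN], [FP, TN]]


def two_sample_ttest(
    values_a,
    values_b,
    variant: str = "welch",
    metric_name: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> GroupComparison:
    """Two-sided two-sample t-test.

    ``welch`` (default) uses the Satterthwaite degrees of freedom; ``pooled``
    assumes equal variances.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("each group needs >= 2 finite values")
    if variant not in ("welch", "pooled"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ParameterError("undefined statistic: zero variance in both groups, equal means")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return GroupComparison(
        metric_name=metric_name,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        alpha=alpha,
    )


def _ellipse_shape(points: np.ndarray):
    center = points.mean(axis=0)
    cov = np.cov(points.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if np.min(eigvals) <= 1e-12 * max(np.max(eigvals), 1.0):
        raise DegenerateGeometryError("points are collinear; covariance is singular")
    # eigh returns ascending order; put the major axis first
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    angle = math.atan2(eigvecs[1, 0], eigvecs[0, 0])
    return center, cov, eigvals, angle


def coverage_ellipse(
    points, coverage_target: float = 0.95, mode: str = "empirical"
) -> CoverageEllipse:
    """Ellipse in the coefficient plane enclosing a target fraction of points.

    ``gaussian`` scales the sample-covariance ellipse by the chi-square(2)
    quantile at ``coverage_target``; ``empirical`` (default) rescales that
    ellipse to the smallest radius whose enclosed fraction of the input
    points is >= the target — matching the descriptive claim that the drawn
    ellipses encircled 95% of each group.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ParameterError("need >= 3 points of shape (n, 2)")
    if not 0 < coverage_target < 1:
        raise ParameterError("coverage_target must be in (0, 1)")
    if mode not in ("gaussian", "empirical"):
        raise ParameterError(f"unknown ellipse mode {mode!r}")

    center, cov, eigvals, angle = _ellipse_shape(pts)
    d = pts - center
    maha2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(cov), d)

    if mode == "gaussian":
        r2 = stats.chi2.ppf(coverage_target, df=2)
    else:
        k = math.ceil(coverage_target * pts.shape[0])
        r2 = float(np.sort(maha2)[k - 1]) * (1 + 1e-12)  # include the kth point
    inside = maha2 <= r2
    return CoverageEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(np.sqrt(eigvals[0] * r2)), float(np.sqrt(eigvals[1] * r2))),
        angle=float(angle),
        coverage_target=coverage_target,
        empirical_coverage=float(inside.mean()),
    )


def classify_by_distance(
    distances,
    labels,
    threshold: float | str = "auto",
    positive_label: str | None = None,
) -> ClassificationReport:
    """Threshold classifier on the centroid-distance statistic.

    The positive class (predicted when distance < threshold) is the impaired
    group, which sits nearer the triangle centroid; by default it is the
    class with the smaller mean distance. ``threshold='auto'`` uses the
    midpoint of the two class means. Sensitivity is the positive-class recall.
    """
    d = np.asarray(distances, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(set(lab.tolist()))
    if len(classes) != 2:
        raise ClassBalanceError(f"need exactly 2 classes, got {classes}")
    means = {c: float(d[lab == c].mean()) for c in classes}
    if positive_label is None:
        positive_label = min(classes, key=lambda c: means[c])
    elif positive_label not in classes:
        raise ParameterError(f"positive_label {positive_label!r} not in {classes}")
    if threshold == "auto":
        thr = float(np.mean(list(means.values())))
    else:
        thr = float(threshold)

    pred_pos = d < thr
    is_pos = lab == positive_label
    tp = int(np.sum(pred_pos & is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    n = tp + fn + fp + tn
    return ClassificationReport(
        threshold=thr,
        positive_label=str(positive_label),
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        confusion=((tp, fn), (fp, tn)),
    )


SUMMARY_METRICS = ("stride_time_s", "phi1", "phi2", "ar_distance")
REGIONS = ("non_oscillatory", "oscillatory", "boundary", "unstable")


def summarize_cohort(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean +/- SD table plus triangle-region fractions.

    ``per_subject`` needs columns ``group_label``, ``stride_time_s``,
    ``phi1``, ``phi2``, ``ar_distance``, ``region``. Single-subject groups
    report SD 0 with ``sd_undefined`` flagged.
    """
    required = {"group_label", "region", *SUMMARY_METRICS}
    missing = required - set(per_subject.columns)
    if missing:
        raise AggregationError(f"per-subject table missing columns: {sorted(missing)}")
    if per_subject.empty:
        raise AggregationError("empty per-subject table")

    rows = []
    for group, gdf in per_subject.groupby("group_label", sort=True):
        n = len(gdf)
        if n == 0:
            raise AggregationError(f"empty group {group!r}")
        for metric in SUMMARY_METRICS:
            vals = gdf[metric].to_numpy(dtype=float)
            rows.append(
                {
                    "group_label": group,
                    "metric": metric,
                    "n": n,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
                    "sd_undefined": n < 2,
                }
            )
        counts = gdf["region"].value_counts()
        for region in REGIONS:
            rows.append(
                {
                    "group_label": group,
                    "metric": f"fraction_{region}",
                    "n": n,
                    "mean": float(counts.get(region, 0)) / n,
                    "sd": float("nan"),
                    "sd_undefined": True,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    per_subject: pd.DataFrame,
    group_a: str,
    group_b: str,
    variant: str = "welch",
    alpha: float = DEFAULT_ALPHA,
) -> list[GroupComparison]:
    """Run the per-metric two-sample t-tests between two groups."""
    out = []
    a_df = per_subject[per_subject["group_label"] == group_a]
    b_df = per_subject[per_subject["group_label"] == group_b]
    for metric in SUMMARY_METRICS:
        out.append(
            two_sample_ttest(
                a_df[metric],
                b_df[metric],
                variant=variant,
                metric_name=metric,
                alpha=alpha,
            )
        )
    return out
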