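"""AR(2) fitting and stationarity-triangle characterization.

Model: ``y_t = delta + phi1 * y_{t-1} + phi2 * y_{t-2} + eps_t`` with white
noise ``eps_t``. The coefficient pair (phi1, phi2) is stationary iff it lies
inside the triangle

    phi1 + phi2 < 1,    phi2 - phi1 < 1,    |phi2| < 1,

with vertices (-2, -1), (2, -1), (0, 1) and centroid (0, -1/3). Inside the
triangle the characteristic roots of ``z^2 - phi1*z - phi2`` are complex —
damped oscillatory dynamics — exactly when the discriminant
``phi1^2 + 4*phi2`` is negative (the region boundary is the parabola
``phi2 = -phi1^2 / 4``, often loosely drawn as a semicircle); two real roots
give non-oscillatory dynamics with two embedded time constants.

The scalar stability statistic is the Euclidean distance from the fitted
coefficient pair to the triangle centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import yule_walker as _sm_yule_walker

from .errors import DegenerateFitError, ParameterError, ShortSeriesError
from .preprocess import DetrendedSeries

#: Centroid of the stationarity triangle.
CENTROID = (0.0, -1.0 / 3.0)

#: Vertices of the stationarity triangle, counter-clockwise.
TRIANGLE_VERTICES = ((-2.0, -1.0), (2.0, -1.0), (0.0, 1.0))

DEFAULT_TOL = 1e-9

MIN_FIT_LENGTH = 30


@dataclass(frozen=True)
class ARFit:
    """Estimated AR(2) parameters for one subject."""

    phi1: float
    phi2: float
    delta: float
    sigma2: float
    n_effective: int
    method: str


@dataclass(frozen=True)
class StabilityAssessment:
    """Triangle placement of one coefficient pair."""

    phi1: float
    phi2: float
    region: str  # unstable | oscillatory | non_oscillatory | boundary
    distance: float
    char_roots: tuple[complex, complex]


@dataclass(frozen=True)
class CorrelogramResult:
    """Sample ACF/PACF used for model-order diagnostics."""

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    ci_halfwidth: float


def fit_ar2(detrended: DetrendedSeries, method: str = "cls") -> ARFit:
    """Fit the AR(2) model to a detrended series.

    ``cls`` (conditional least squares, the default) regresses ``y_t`` on
    ``(1, y_{t-1}, y_{t-2})`` over t = 2..n-1; ``sigma2`` is the unbiased
    residual variance. ``yule_walker`` solves the order-2 Yule-Walker
    equations from biased sample autocovariances; ``sigma2`` is the implied
    innovation variance and ``delta`` is induced from the sample mean.

    Raises
    ------
    ShortSeriesError
        Fewer than 30 residuals.
    DegenerateFitError
        Singular design (e.g. constant residuals).
    """
    y = np.asarray(detrended.residuals, dtype=float)
    n = y.size
    if n < MIN_FIT_LENGTH:
        raise ShortSeriesError(f"need >= {MIN_FIT_LENGTH} residuals, got {n}")

    if method == "cls":
        Y = y[2:]
        X = np.column_stack([np.ones(n - 2), y[1:-1], y[:-2]])
        # rank check catches constant residuals (lagged columns collinear
        # with the intercept)
        if np.linalg.matrix_rank(X) < 3:
            raise DegenerateFitError("singular AR(2) design matrix")
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        delta, phi1, phi2 = beta
        resid = Y - X @ beta
        n_eff = n - 2
        dof = n_eff - 3
        sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
        return ARFit(
            phi1=float(phi1),
            phi2=float(phi2),
            delta=float(delta),
            sigma2=sigma2,
            n_effective=n_eff,
            method="cls",
        )
    if method == "yule_walker":
        if np.allclose(y, y[0]):
            raise DegenerateFitError("constant residuals")
        rho, sigma = _sm_yule_walker(y, order=2, method="mle", demean=True)
        phi1, phi2 = (float(r) for r in rho)
        ybar = float(y.mean())
        return ARFit(
            phi1=phi1,
            phi2=phi2,
            delta=ybar * (1.0 - phi1 - phi2),
            sigma2=float(sigma) ** 2,
            n_effective=n,
            method="yule_walker",
        )
    raise ParameterError(f"unknown fit method {method!r}")


def correlogram(detrended: DetrendedSeries, max_lag: int = 20) -> CorrelogramResult:
    """Biased sample ACF and Durbin-Levinson PACF up to ``max_lag``.

    ``ci_halfwidth`` is the usual white-noise band 1.96 / sqrt(n).
    """
    y = np.asarray(detrended.residuals, dtype=float)
    n = y.size
    if max_lag >= n / 2:
        raise ParameterError(f"max_lag={max_lag} must be < n/2 = {n / 2}")
    x = y - y.mean()
    c0 = float(x @ x) / n
    if c0 == 0:
        raise DegenerateFitError("zero-variance series has no correlogram")
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = float(x[:-k] @ x[k:]) / n / c0

    # Durbin-Levinson recursion: pacf[k] is the last coefficient of the
    # order-k Yule-Walker solution.
    pacf = np.empty(max_lag + 1)
    pacf[0] = 1.0
    phi_prev = np.zeros(0)
    for k in range(1, max_lag + 1):
        if k == 1:
            a = acf[1]
            phi_prev = np.array([a])
        else:
            num = acf[k] - phi_prev @ acf[k - 1 : 0 : -1]
            den = 1.0 - phi_prev @ acf[1:k]
            a = num / den
            phi_prev = np.append(phi_prev - a * phi_prev[::-1], a)
        pacf[k] = a
    return CorrelogramResult(
        lags=np.arange(max_lag + 1),
        acf=acf,
        pacf=pacf,
        ci_halfwidth=1.96 / math.sqrt(n),
    )


def ar_distance(phi1: float, phi2: float) -> float:
    """Euclidean distance from (phi1, phi2) to the triangle centroid (0, -1/3)."""
    return math.hypot(phi1 - CENTROID[0], phi2 - CENTROID[1])


def characteristic_roots(phi1: float, phi2: float) -> tuple[complex, complex]:
    """Roots of ``z^2 - phi1*z - phi2``; both inside the unit circle iff stationary."""
    r = np.roots([1.0, -phi1, -phi2])
    roots = sorted((complex(v) for v in r), key=lambda z: (z.real, z.imag))
    if len(roots) == 1:  # phi2 == 0 collapses the degree
        roots.append(complex(0.0))
        roots.sort(key=lambda z: (z.real, z.imag))
    return roots[0], roots[1]


def classify_stability(
    phi1: float, phi2: float, tol: float = DEFAULT_TOL
) -> StabilityAssessment:
    """Place a coefficient pair on the stationarity triangle.

    Returns region ``unstable`` outside the triangle, ``oscillatory`` inside
    with complex characteristic roots (discriminant < -tol),
    ``non_oscillatory`` inside with two real roots (discriminant > tol), and
    ``boundary`` when any criterion sits within ``tol`` of equality.
    """
    if tol <= 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    criteria = (
        1.0 - (phi1 + phi2),  # phi1 + phi2 < 1
        1.0 - (phi2 - phi1),  # phi2 - phi1 < 1
        1.0 - abs(phi2),      # |phi2| < 1
    )
    roots = characteristic_roots(phi1, phi2)
    dist = ar_distance(phi1, phi2)
    if any(abs(c) <= tol for c in criteria):
        region = "boundary"
    elif any(c < 0 for c in criteria):
        region = "unstable"
    else:
        disc = phi1 * phi1 + 4.0 * phi2
        if abs(disc) <= tol:
            region = "boundary"
        elif disc < 0:
            region = "oscillatory"
        else:
            region = "non_oscillatory"
    return StabilityAssessment(
        phi1=float(phi1),
        phi2=float(phi2),
        region=region,
        distance=dist,
        char_roots=roots,
    )


def assess_fit(fit: ARFit, tol: float = DEFAULT_TOL) -> StabilityAssessment:
    """Classify a fitted coefficient pair."""
    return classify_stability(fit.phi1, fit.phi2, tol=tol)


def triangle_geometry() -> tuple[tuple[tuple[float, float], ...], tuple[float, float]]:
    """Vertices and centroid of the stationarity triangle."""
    return TRIANGLE_VERTICES, CENTROID


def is_stationary(phi1: float, phi2: float, tol: float = 0.0) -> bool:
    """True iff (phi1, phi2) satisfies all three stationarity inequalities
    strictly beyond ``tol``."""
    return (
        phi1 + phi2 < 1.0 - tol
        and phi2 - phi1 < 1.0 - tol
        and abs(phi2) < 1.0 - tol
    )


def violated_inequality(phi1: float, phi2: float) -> str | None:
    """Name the first violated stationarity inequality, or None if stationary."""
    if phi1 + phi2 >= 1.0:
        return f"phi1 + phi2 = {phi1 + phi2:.4g} >= 1"
    if phi2 - phi1 >= 1.0:
        return f"phi2 - phi1 = {phi2 - phi1:.4g} >= 1"
    if abs(phi2) >= 1.0:
        return f"|phi2| = {abs(phi2):.4g} >= 1"
    return None
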