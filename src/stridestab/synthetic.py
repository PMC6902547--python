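"""Synthetic stride-time cohort generator.

Each subject is a stationary zero-mean AR(2) process with Gaussian
innovations, shifted by a subject-level mean stride time and an optional
linear trend:

    x_t = mean + slope * t + y_t,
    y_t = phi1 * y_{t-1} + phi2 * y_{t-2} + eps_t,   eps_t ~ N(0, sd^2).

Cohorts draw per-subject (phi1, phi2) from independent normals truncated to
the stationarity triangle by rejection, and per-subject mean stride times
from a normal floored at a physiologic minimum. Generation is a pure
function of the spec (master seed + subject index), so fixtures are stable
under cohort edits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import lfilter

from .ar import is_stationary, violated_inequality
from .errors import NonStationaryError, ParameterError, ShortSeriesError
from .gait_io import StrideTimeSeries

#: Steps discarded before the recorded series so the AR component is
#: approximately stationary; generous for any pair well inside the triangle.
BURN_IN = 200

#: Floor applied to subject-level mean stride times (physiologic positivity).
STRIDE_MEAN_FLOOR_S = 0.4

MIN_STRIDES = 30

#: Cap on rejection-sampling draws per subject.
MAX_REJECTION_DRAWS = 10_000


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic group.

    The defaults for the bundled control-like and HD-like groups mirror the
    published cohort summaries: coefficient means (0.4, 0.1) vs (0.1, 0.0),
    stride-time means 1.1 s vs 1.2 s, with matching between-subject SDs. The
    innovation SDs are tuning knobs (the source data's innovation variance is
    unpublished), chosen to land the overall stride-time SDs near the
    printed values.
    """

    group_label: str
    n_subjects: int
    phi1_mean: float
    phi1_sd: float
    phi2_mean: float
    phi2_sd: float
    stride_mean_s: float
    stride_mean_sd_s: float
    innovation_sd_s: float
    n_strides: int = 250
    trend_slope_s_per_stride: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.n_strides < MIN_STRIDES:
            raise ParameterError(f"n_strides must be >= {MIN_STRIDES}")
        for name in ("phi1_sd", "phi2_sd", "stride_mean_sd_s", "innovation_sd_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not is_stationary(self.phi1_mean, self.phi2_mean):
            raise NonStationaryError(
                "mean coefficient pair is non-stationary: "
                f"{violated_inequality(self.phi1_mean, self.phi2_mean)}"
            )


def simulate_subject(
    phi1: float,
    phi2: float,
    stride_mean: float,
    innovation_sd: float,
    trend_slope: float,
    n_strides: int,
    seed: int,
    subject_id: str = "sim",
    group_label: str = "simulated",
) -> StrideTimeSeries:
    """Simulate one subject's stride-time series.

    The AR recursion is run for ``BURN_IN + n_strides`` steps from zero
    initial conditions and the burn-in is discarded. Identical arguments
    (seed included) return bitwise-identical series.

    Raises
    ------
    NonStationaryError
        (phi1, phi2) outside the stationarity triangle, with the violated
        inequality named.
    ShortSeriesError
        ``n_strides`` below the 30-stride minimum.
    """
    if not is_stationary(phi1, phi2):
        raise NonStationaryError(
            f"({phi1}, {phi2}) is non-stationary: {violated_inequality(phi1, phi2)}"
        )
    if n_strides < MIN_STRIDES:
        raise ShortSeriesError(f"n_strides must be >= {MIN_STRIDES}, got {n_strides}")
    if innovation_sd < 0:
        raise ParameterError("innovation_sd must be >= 0")

    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, innovation_sd, size=BURN_IN + n_strides)
    # y_t - phi1 y_{t-1} - phi2 y_{t-2} = eps_t  <=>  AR filter of the noise
    y = lfilter([1.0], [1.0, -phi1, -phi2], eps)[BURN_IN:]
    t = np.arange(n_strides, dtype=float)
    strides = stride_mean + trend_slope * t + y
    return StrideTimeSeries(
        subject_id=subject_id,
        group_label=group_label,
        foot="left",
        stride_times=strides,
        source=f"simulate_subject(seed={seed})",
    )


def _draw_subject_params(spec: CohortSpec, rng: np.random.Generator) -> tuple[float, float, float]:
    """Draw one subject's (phi1, phi2, stride mean), truncated to validity."""
    for _ in range(MAX_REJECTION_DRAWS):
        phi1 = rng.normal(spec.phi1_mean, spec.phi1_sd)
        phi2 = rng.normal(spec.phi2_mean, spec.phi2_sd)
        if is_stationary(phi1, phi2):
            break
    else:
        raise ParameterError(
            f"{spec.group_label}: could not draw a stationary coefficient pair in "
            f"{MAX_REJECTION_DRAWS} attempts — means too close to the triangle boundary"
        )
    mean = max(rng.normal(spec.stride_mean_s, spec.stride_mean_sd_s), STRIDE_MEAN_FLOOR_S)
    return phi1, phi2, mean


@dataclass(frozen=True)
class SubjectParams:
    """One subject's drawn generative parameters."""

    phi1: float
    phi2: float
    stride_mean_s: float
    series_seed: int


def cohort_parameters(spec: CohortSpec) -> list[SubjectParams]:
    """Draw the per-subject generative parameters for a cohort.

    Subject ``i`` uses the counter-based seed ``master_seed + i``, so
    inserting or removing later subjects does not reshuffle earlier ones.
    """
    params = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(spec.master_seed + i)
        phi1, phi2, mean = _draw_subject_params(spec, rng)
        params.append(
            SubjectParams(
                phi1=phi1,
                phi2=phi2,
                stride_mean_s=mean,
                series_seed=int(rng.integers(0, 2**63 - 1)),
            )
        )
    return params


def simulate_cohort(spec: CohortSpec) -> list[StrideTimeSeries]:
    """Simulate a full cohort from a :class:`CohortSpec`.

    Generation is deterministic in the spec; see :func:`cohort_parameters`
    for the per-subject seeding scheme.
    """
    out = []
    for i, p in enumerate(cohort_parameters(spec)):
        series = simulate_subject(
            phi1=p.phi1,
            phi2=p.phi2,
            stride_mean=p.stride_mean_s,
            innovation_sd=spec.innovation_sd_s,
            trend_slope=spec.trend_slope_s_per_stride,
            n_strides=spec.n_strides,
            seed=p.series_seed,
            subject_id=f"{spec.group_label}{i + 1}",
            group_label=spec.group_label,
        )
        out.append(series)
    return out


def ar2_stationary_variance(phi1: float, phi2: float, sigma2: float) -> float:
    """Closed-form stationary variance of a zero-mean AR(2) process."""
    if not is_stationary(phi1, phi2):
        raise NonStationaryError(f"({phi1}, {phi2}) has no stationary variance")
    return sigma2 * (1 - phi2) / ((1 + phi2) * ((1 - phi2) ** 2 - phi1**2))


def default_cohort_specs(master_seed: int = 0) -> list[CohortSpec]:
    """Bundled control-like and HD-like cohort specs.

    Sizes 16 vs 20 and the coefficient / stride-time distributions follow the
    published group summaries; innovation SDs are the documented tuning
    defaults (0.03 s control, 0.08 s HD).
    """
    return [
        CohortSpec(
            group_label="control",
            n_subjects=16,
            phi1_mean=0.4,
            phi1_sd=0.1,
            phi2_mean=0.1,
            phi2_sd=0.1,
            stride_mean_s=1.1,
            stride_mean_sd_s=0.1,
            innovation_sd_s=0.03,
            master_seed=master_seed,
        ),
        CohortSpec(
            group_label="huntington",
            n_subjects=20,
            phi1_mean=0.1,
            phi1_sd=0.2,
            phi2_mean=0.0,
            phi2_sd=0.1,
            stride_mean_s=1.2,
            stride_mean_sd_s=0.2,
            innovation_sd_s=0.08,
            master_seed=master_seed + 1_000_000,
        ),
    ]


def load_cohort_specs(path: str | Path, master_seed: int | None = None) -> list[CohortSpec]:
    """Load cohort specs from a YAML (or JSON — YAML superset) config.

    Layout: top-level key ``cohorts`` holding a list of mappings whose keys
    match :class:`CohortSpec` fields. ``master_seed`` overrides every
    cohort's seed base when given (cohort i gets ``master_seed + i * 10**6``).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "cohorts" not in doc:
        raise ParameterError(f"{path}: expected a top-level 'cohorts' list")
    specs = []
    for i, entry in enumerate(doc["cohorts"]):
        if master_seed is not None:
            entry = {**entry, "master_seed": master_seed + i * 1_000_000}
        specs.append(CohortSpec(**entry))
    return specs
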