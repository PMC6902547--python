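"""End-to-end orchestration: ingest/simulate -> preprocess -> fit ->
stability -> group statistics -> artifacts.

Artifacts written to the output directory:

* ``per_subject_fits.csv`` — one row per analyzed subject (coefficients,
  distance, region, stride-time summary);
* ``exclusions.csv`` — subjects that failed a stage, with the reason;
* ``group_summary.csv`` — per-group mean +/- SD table and region fractions;
* ``comparisons.json`` — t-tests, ellipses, and the (reconstructed)
  distance-threshold classification report;
* ``triangle.png`` — the stationarity-triangle figure (optional).

Every input subject lands either in the fits table or in the exclusions log.
Runs are pure functions of the configuration (master seed included), and CSV
outputs are byte-stable across repeated runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ar, gait_io, groupstats, preprocess, synthetic
from .errors import DataError, DegenerateGeometryError, ParameterError, StridestabError

logger = logging.getLogger(__name__)

INPUT_MODES = ("simulate", "gaitndd_dir", "internal_csv")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; exactly one input mode is used."""

    mode: str = "simulate"
    input_dir: str | None = None  # gaitndd_dir / internal_csv modes
    cohort_config: str | None = None  # simulate mode; None -> bundled defaults
    output_dir: str = "stridestab_out"
    foot: str = "left"
    detrend_regressor: str = "index"
    outliers_enabled: bool = False
    outlier_k: float = 3.0
    fit_method: str = "cls"
    tol: float = ar.DEFAULT_TOL
    ttest_variant: str = "welch"
    ellipse_mode: str = "empirical"
    ellipse_coverage: float = 0.95
    classifier_threshold: float | str = "auto"
    master_seed: int = 0
    make_plot: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ParameterError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")
        if self.mode != "simulate" and not self.input_dir:
            raise ParameterError(f"mode {self.mode!r} requires input_dir")


@dataclass
class PipelineResult:
    per_subject: pd.DataFrame
    summary: pd.DataFrame
    comparisons: dict
    exclusions: pd.DataFrame
    artifacts: dict[str, Path] = field(default_factory=dict)


def _load_subjects(config: PipelineConfig) -> list[gait_io.StrideTimeSeries]:
    if config.mode == "simulate":
        if config.cohort_config:
            specs = synthetic.load_cohort_specs(
                config.cohort_config, master_seed=config.master_seed
            )
        else:
            specs = synthetic.default_cohort_specs(master_seed=config.master_seed)
        subjects: list[gait_io.StrideTimeSeries] = []
        for spec in specs:
            subjects.extend(synthetic.simulate_cohort(spec))
        return subjects
    if config.mode == "gaitndd_dir":
        return gait_io.read_gaitndd_dir(config.input_dir, foot=config.foot)
    # internal_csv: every *.csv in the directory is one subject
    paths = sorted(Path(config.input_dir).glob("*.csv"))
    return [gait_io.read_internal_csv(p) for p in paths]


def analyze_subject(
    series: gait_io.StrideTimeSeries, config: PipelineConfig
) -> dict:
    """Run preprocess + fit + stability for one subject; returns a fits row."""
    detrended = preprocess.preprocess_series(
        series,
        outliers_enabled=config.outliers_enabled,
        outlier_k=config.outlier_k,
        regressor=config.detrend_regressor,
    )
    fit = ar.fit_ar2(detrended, method=config.fit_method)
    assessment = ar.assess_fit(fit, tol=config.tol)
    logger.info(
        "%s: n=%d drops=%d method=%s phi=(%.3f, %.3f) region=%s",
        series.subject_id,
        detrended.n,
        detrended.outliers_removed,
        fit.method,
        fit.phi1,
        fit.phi2,
        assessment.region,
    )
    return {
        "subject_id": series.subject_id,
        "group_label": series.group_label,
        "foot": series.foot,
        "n_strides": detrended.n,
        "outliers_removed": detrended.outliers_removed,
        "stride_time_s": float(series.stride_times.mean()),
        "stride_time_sd_s": float(series.stride_times.std(ddof=1)),
        "trend_slope": detrended.trend_slope,
        "phi1": fit.phi1,
        "phi2": fit.phi2,
        "delta": fit.delta,
        "sigma2": fit.sigma2,
        "ar_distance": assessment.distance,
        "region": assessment.region,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts.

    Per-subject failures are logged to the exclusions table and the run
    continues; an empty analyzable cohort raises :class:`DataError`.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    subjects = _load_subjects(config)
    rows, excluded = [], []
    for series in subjects:
        try:
            rows.append(analyze_subject(series, config))
        except StridestabError as exc:
            logger.warning("excluding %s: %s", series.subject_id, exc)
            excluded.append(
                {
                    "subject_id": series.subject_id,
                    "group_label": series.group_label,
                    "reason": f"{type(exc).__name__}: {exc}",
                }
            )
    if not rows:
        raise DataError("no analyzable subjects in input")
    assert len(rows) + len(excluded) == len(subjects)

    per_subject = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded, columns=["subject_id", "group_label", "reason"])
    summary = groupstats.summarize_cohort(per_subject)

    comparisons: dict = {
        "note": (
            "classification is a distance-threshold reconstruction; the source "
            "analysis does not define its accuracy/sensitivity/specificity procedure"
        ),
        "ttest_variant": config.ttest_variant,
        "groups": sorted(per_subject["group_label"].unique().tolist()),
        "tests": [],
        "ellipses": {},
        "classification": None,
    }
    groups = comparisons["groups"]
    group_sizes = per_subject["group_label"].value_counts()
    if len(groups) == 2 and all(group_sizes[g] >= 2 for g in groups):
        tests = groupstats.compare_groups(
            per_subject, groups[0], groups[1], variant=config.ttest_variant
        )
        comparisons["tests"] = [dataclasses.asdict(t) for t in tests]
        report = groupstats.classify_by_distance(
            per_subject["ar_distance"],
            per_subject["group_label"],
            threshold=config.classifier_threshold,
        )
        comparisons["classification"] = dataclasses.asdict(report)
    else:
        logger.info("%d groups present; pairwise tests skipped", len(groups))

    ellipses = {}
    for group, gdf in per_subject.groupby("group_label"):
        if len(gdf) >= 3:
            try:
                e = groupstats.coverage_ellipse(
                    gdf[["phi1", "phi2"]].to_numpy(),
                    coverage_target=config.ellipse_coverage,
                    mode=config.ellipse_mode,
                )
            except DegenerateGeometryError as exc:
                logger.warning("no ellipse for %s: %s", group, exc)
                continue
            ellipses[group] = e
            comparisons["ellipses"][group] = dataclasses.asdict(e)

    artifacts: dict[str, Path] = {}
    fits_path = outdir / "per_subject_fits.csv"
    per_subject.to_csv(fits_path, index=False, float_format="%.10g")
    artifacts["fits"] = fits_path

    excl_path = outdir / "exclusions.csv"
    exclusions.to_csv(excl_path, index=False)
    artifacts["exclusions"] = excl_path

    summary_path = outdir / "group_summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.10g")
    artifacts["summary"] = summary_path

    comp_path = outdir / "comparisons.json"
    with open(comp_path, "w") as fh:
        json.dump(comparisons, fh, indent=2, sort_keys=True)
    artifacts["comparisons"] = comp_path

    if config.make_plot:
        from .plotting import plot_triangle

        fig_path = outdir / "triangle.png"
        plot_triangle(per_subject, ellipses=ellipses, path=fig_path)
        artifacts["figure"] = fig_path

    return PipelineResult(
        per_subject=per_subject,
        summary=summary,
        comparisons=comparisons,
        exclusions=exclusions,
        artifacts=artifacts,
    )
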