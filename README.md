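# stridestab

Stride-time pattern stability analysis via second-order autoregressive
modeling. The pipeline builds a per-subject stride-interval time series,
removes a linear trend, fits an AR(2) model

```
y_t = delta + phi1 * y_{t-1} + phi2 * y_{t-2} + eps_t
```

and places each subject's coefficient pair on the AR(2) **stationarity
triangle** (vertices (-2,-1), (2,-1), (0,1)). Pairs inside the triangle with
complex characteristic roots (discriminant `phi1^2 + 4*phi2 < 0`) are
*oscillatory*; real roots are *non-oscillatory*; pairs outside the triangle
are *unstable*. The scalar stability statistic is the Euclidean distance
from the fitted pair to the triangle centroid `(0, -1/3)`. Group-level
tooling provides two-sample t-tests, 95% coverage ellipses in the
coefficient plane, a distance-threshold classifier, and a summary table.

A synthetic cohort generator (stationary AR(2) + trend + between-subject
heterogeneity, truncated to the triangle by rejection sampling) makes the
whole pipeline testable without any data download.

## CLI

```sh
# simulate the bundled control-like / HD-like cohorts to internal CSVs
stridestab simulate --out sim/ --seed 1

# full pipeline on those CSVs (fits, summary, comparisons, triangle figure)
stridestab analyze --mode internal_csv --input-dir sim/ --out results/

# or end to end in one step from the built-in synthetic cohorts
stridestab analyze --mode simulate --out results/ --seed 1

# re-summarize / re-plot a fits table
stridestab report --fits results/per_subject_fits.csv --out summary.csv
stridestab plot --fits results/per_subject_fits.csv --out triangle.png
```

Exit codes: 0 success, 2 configuration error, 3 data error.

To analyze the public stride-interval database instead, place its `*.ts`
files (whitespace-delimited; elapsed time, left stride, right stride, ...)
in a directory and use `--mode gaitndd_dir --input-dir <dir>`. Group labels
are inferred from filename prefixes (`control` / `hunt` / `als` / `park`).
Which limb the original analysis used is unstated; `--foot left` is the
default, with `right` and `average` available.

Custom synthetic cohorts are configured in YAML (see
`stridestab.synthetic.CohortSpec` for the field list):

```yaml
cohorts:
  - group_label: control
    n_subjects: 16
    phi1_mean: 0.4
    phi1_sd: 0.1
    phi2_mean: 0.1
    phi2_sd: 0.1
    stride_mean_s: 1.1
    stride_mean_sd_s: 0.1
    innovation_sd_s: 0.03
```

## Layout

| module | role |
| --- | --- |
| `stridestab.synthetic` | cohort specs + AR(2) gait simulator |
| `stridestab.gait_io` | accession / internal-CSV readers and writers |
| `stridestab.preprocess` | outlier filter (off by default) + linear detrend |
| `stridestab.ar` | AR(2) fits (CLS / Yule-Walker), ACF/PACF, triangle classification, centroid distance |
| `stridestab.groupstats` | t-tests, coverage ellipses, distance classifier, group summary |
| `stridestab.pipeline`, `stridestab.cli` | orchestration and command-line verbs |

Note: the distance-threshold classifier is a declared reconstruction — the
original report lists accuracy/sensitivity/specificity among its metrics
without defining the procedure — and its output is labeled as such.
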