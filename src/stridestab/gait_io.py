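"""Read/write stride-interval series.

Two dialects are supported:

* the public accession's whitespace-delimited layout (one subject per file,
  elapsed time in column 0, left/right stride intervals in columns 1/2), and
* an internal RFC-4180 CSV with header
  ``subject_id,group_label,foot,stride_index,stride_time_s``.

Parsing never reorders strides.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import SchemaError, ShortSeriesError

logger = logging.getLogger(__name__)

#: Minimum number of strides for any series handed to the fitting stage.
MIN_SERIES_LENGTH = 30

#: Column layout of the accession files (only the columns we consume).
DEFAULT_COLUMN_MAP: Mapping[str, int] = {
    "elapsed": 0,
    "left_stride": 1,
    "right_stride": 2,
}

VALID_FEET = ("left", "right", "average")

_GROUP_PREFIXES = {
    "control": "control",
    "hunt": "huntington",
    "als": "als",
    "park": "park",
}


@dataclass(frozen=True)
class StrideTimeSeries:
    """One subject's ordered stride intervals.

    Attributes
    ----------
    subject_id : str
        Identifier, typically the source filename stem.
    group_label : str
        Cohort label, e.g. ``control`` or ``huntington``.
    foot : str
        Which limb's stride series: ``left``, ``right`` or ``average``.
    stride_times : np.ndarray
        Stride intervals in seconds, in recording order; all finite and > 0.
    elapsed_times : np.ndarray | None
        Optional cumulative protocol time per stride, strictly increasing.
    source : str
        Provenance note (file path or simulation tag).
    """

    subject_id: str
    group_label: str
    foot: str
    stride_times: np.ndarray
    elapsed_times: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "stride_times", np.asarray(self.stride_times, dtype=float)
        )
        if self.elapsed_times is not None:
            elapsed = np.asarray(self.elapsed_times, dtype=float)
            object.__setattr__(self, "elapsed_times", elapsed)
            if elapsed.size and np.any(np.diff(elapsed) <= 0):
                raise ValueError("elapsed_times must be strictly increasing")
        if self.foot not in VALID_FEET:
            raise ValueError(f"foot must be one of {VALID_FEET}, got {self.foot!r}")

    def __len__(self) -> int:
        return int(self.stride_times.size)


def infer_group_from_filename(path: str | Path) -> str:
    """Map an accession filename prefix (control/hunt/als/park) to a label."""
    stem = Path(path).stem.lower()
    for prefix, label in _GROUP_PREFIXES.items():
        if stem.startswith(prefix):
            return label
    return "unknown"


def read_gaitndd_file(
    path: str | Path,
    foot: str = "left",
    column_map: Mapping[str, int] | None = None,
    group_label: str | None = None,
    min_length: int = MIN_SERIES_LENGTH,
) -> StrideTimeSeries:
    """Read one subject's whitespace-delimited accession file.

    Rows whose stride value is non-numeric or non-positive are dropped with a
    logged count.

    Parameters
    ----------
    path : path-like
        Accession file with >= 2 whitespace-delimited numeric columns.
    foot : {"left", "right", "average"}
        Which stride-interval column to return; ``average`` is the per-stride
        mean of the two columns.
    column_map : mapping, optional
        Overrides the default column indices ``elapsed``, ``left_stride``,
        ``right_stride``.
    group_label : str, optional
        Overrides the label inferred from the filename prefix.
    min_length : int
        Minimum number of valid rows; the fitting default is 30, but toy
        files can be read with a smaller floor.

    Raises
    ------
    OSError
        Unreadable file.
    SchemaError
        Fewer columns than the column map references.
    ShortSeriesError
        Fewer than 30 valid rows remain after cleaning.
    """
    path = Path(path)
    if foot not in VALID_FEET:
        raise SchemaError(f"foot must be one of {VALID_FEET}, got {foot!r}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if tokens:
                rows.append(tokens)
    if not rows:
        raise ShortSeriesError(f"{path}: empty file")

    ncol = min(len(r) for r in rows)
    if foot == "average":
        needed = [cmap["elapsed"], cmap["left_stride"], cmap["right_stride"]]
    else:
        needed = [cmap["elapsed"], cmap[f"{foot}_stride"]]
    if max(needed) >= ncol:
        raise SchemaError(
            f"{path}: column map references column {max(needed)} "
            f"but file has only {ncol} columns"
        )

    def _col(idx: int) -> np.ndarray:
        out = np.full(len(rows), np.nan)
        for i, r in enumerate(rows):
            try:
                out[i] = float(r[idx])
            except (ValueError, IndexError):
                pass
        return out

    elapsed = _col(cmap["elapsed"])
    if foot == "average":
        left = _col(cmap["left_stride"])
        right = _col(cmap["right_stride"])
        stride = (left + right) / 2.0
    else:
        stride = _col(cmap[f"{foot}_stride"])

    valid = np.isfinite(stride) & (stride > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("%s: dropped %d invalid stride rows", path.name, n_dropped)
    stride = stride[valid]
    elapsed = elapsed[valid]

    if stride.size < min_length:
        raise ShortSeriesError(
            f"{path}: only {stride.size} valid strides (< {min_length})"
        )

    elapsed_out = elapsed if np.all(np.isfinite(elapsed)) and np.all(np.diff(elapsed) > 0) else None
    return StrideTimeSeries(
        subject_id=path.stem,
        group_label=group_label or infer_group_from_filename(path),
        foot=foot,
        stride_times=stride,
        elapsed_times=elapsed_out,
        source=str(path),
    )


INTERNAL_CSV_HEADER = ["subject_id", "group_label", "foot", "stride_index", "stride_time_s"]


def write_internal_csv(series: StrideTimeSeries, path: str | Path) -> None:
    """Write a series in the internal CSV dialect (one row per stride)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INTERNAL_CSV_HEADER)
        for i, x in enumerate(series.stride_times):
            writer.writerow(
                [series.subject_id, series.group_label, series.foot, i, repr(float(x))]
            )


def read_internal_csv(path: str | Path) -> StrideTimeSeries:
    """Read a series written by :func:`write_internal_csv`.

    Non-contiguous stride indices are accepted with a warning; row order is
    preserved regardless.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header") from None
        if [h.strip() for h in header] != INTERNAL_CSV_HEADER:
            raise SchemaError(
                f"{path}: expected header {INTERNAL_CSV_HEADER}, got {header}"
            )
        rows = [r for r in reader if r]

    subject_id = rows[0][0] if rows else path.stem
    group_label = rows[0][1] if rows else "unknown"
    foot = rows[0][2] if rows else "left"
    indices = np.array([int(r[3]) for r in rows], dtype=int)
    stride = np.array([float(r[4]) for r in rows], dtype=float)
    if rows and not np.array_equal(indices, np.arange(indices[0], indices[0] + len(indices))):
        warnings.warn(
            f"{path}: non-contiguous stride_index; order preserved as stored",
            stacklevel=2,
        )
    return StrideTimeSeries(
        subject_id=subject_id,
        group_label=group_label,
        foot=foot,
        stride_times=stride,
        source=str(path),
    )


def read_gaitndd_dir(
    directory: str | Path,
    foot: str = "left",
    groups: Sequence[str] | None = None,
) -> list[StrideTimeSeries]:
    """Read every ``*.ts`` accession file in a directory, sorted by subject.

    Files are sorted by (prefix, numeric suffix) so ``control2`` precedes
    ``control10``. ``groups`` restricts to the given inferred labels.
    """
    directory = Path(directory)
    paths = sorted(
        directory.glob("*.ts"),
        key=lambda p: (
            re.sub(r"\d+$", "", p.stem),
            int(re.search(r"(\d+)$", p.stem).group(1)) if re.search(r"(\d+)$", p.stem) else 0,
        ),
    )
    out = []
    for p in paths:
        label = infer_group_from_filename(p)
        if groups is not None and label not in groups:
            continue
        out.append(read_gaitndd_file(p, foot=foot))
    return out
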