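"""Stationarity-triangle figure: region shading, per-group points, ellipses."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse, Polygon

from .ar import CENTROID, TRIANGLE_VERTICES
from .groupstats import CoverageEllipse

_GROUP_COLORS = ("tab:blue", "tab:pink", "tab:green", "tab:orange", "tab:purple")
_GROUP_MARKERS = ("o", "s", "^", "D", "v")


def plot_triangle(
    per_subject: pd.DataFrame,
    ellipses: dict[str, CoverageEllipse] | None = None,
    path: str | Path | None = None,
    title: str = "AR(2) stationarity triangle",
):
    """Draw the triangle, the oscillatory-region boundary, fitted coefficient
    pairs per group, and optional coverage ellipses.

    The oscillatory boundary is drawn as the exact parabola
    ``phi2 = -phi1^2/4`` (complex characteristic roots below it).
    """
    fig, ax = plt.subplots(figsize=(7, 6))

    tri = Polygon(
        TRIANGLE_VERTICES, closed=True, fill=False, edgecolor="black", linewidth=1.5
    )
    ax.add_patch(tri)
    x = np.linspace(-2, 2, 400)
    ax.plot(x, -(x**2) / 4.0, color="gray", linestyle="--", linewidth=1.0,
            label="oscillatory boundary")
    ax.fill_between(x, -(x**2) / 4.0, -1.0, color="gray", alpha=0.12)
    ax.plot(*CENTROID, marker="+", color="black", markersize=12, mew=2,
            label="centroid (0, -1/3)")

    for i, (group, gdf) in enumerate(per_subject.groupby("group_label", sort=True)):
        color = _GROUP_COLORS[i % len(_GROUP_COLORS)]
        marker = _GROUP_MARKERS[i % len(_GROUP_MARKERS)]
        ax.scatter(gdf["phi1"], gdf["phi2"], s=35, color=color, marker=marker,
                   label=group, zorder=3)
        if ellipses and group in ellipses:
            e = ellipses[group]
            ax.add_patch(
                Ellipse(
                    e.center,
                    width=2 * e.semi_axes[0],
                    height=2 * e.semi_axes[1],
                    angle=math.degrees(e.angle),
                    fill=False,
                    edgecolor=color,
                    linewidth=1.5,
                )
            )

    ax.set_xlim(-2.3, 2.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_xlabel(r"$\phi_1$ (AR1 coefficient)")
    ax.set_ylabel(r"$\phi_2$ (AR2 coefficient)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    ax.set_aspect("equal")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
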