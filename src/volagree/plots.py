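"""Agreement figures: per-quartile deviation scatters and the sliding-window band."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless rendering for batch reports
import matplotlib.pyplot as plt

from .agreement import subject_stats
from .data import AnnotationMatrix
from .strata import STRATUM_LABELS, StratumAssignment

__all__ = ["plot_agreement", "plot_window_curve"]

_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*"]


def plot_agreement(
    matrix: AnnotationMatrix,
    assignment: StratumAssignment | None = None,
    stratum_table=None,
    reference_pct: float = 20.0,
):
    """Per-group scatter of each measurement's percent deviation from its
    subject mean versus the subject mean volume.

    One panel per stratum (or a single panel without an assignment), one
    grey marker style per observer, the group LOAM% as solid horizontal
    lines and the conventional ±``reference_pct`` limit as red dashed lines.
    Deviations within a subject sum to zero by construction.
    """
    stats_df = subject_stats(matrix)
    arr = matrix.to_array()
    dev_pct = 100.0 * (arr - arr.mean(axis=1, keepdims=True)) / arr.mean(axis=1, keepdims=True)

    groups = (
        [(lab, assignment.subjects_in(lab)) for lab in STRATUM_LABELS]
        if assignment is not None
        else [("all", list(matrix.subject_ids))]
    )
    groups = [(lab, mem) for lab, mem in groups if mem]
    ncols = min(2, len(groups))
    nrows = int(np.ceil(len(groups) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(5.5 * ncols, 4 * nrows), squeeze=False)

    loam_by_group = {}
    if stratum_table is not None and len(stratum_table):
        loam_by_group = dict(zip(stratum_table["stratum"], stratum_table["loam_pct"]))

    pos = {s: i for i, s in enumerate(matrix.subject_ids)}
    greys = [str(gv) for gv in np.linspace(0.0, 0.6, matrix.n_observers)]
    for ax, (lab, members) in zip(axes.ravel(), groups):
        idx = [pos[s] for s in members]
        x = stats_df["mean_volume"].to_numpy()[idx]
        for j, obs in enumerate(matrix.observer_ids):
            ax.scatter(
                x,
                dev_pct[idx, j],
                marker=_MARKERS[j % len(_MARKERS)],
                color=greys[j],
                s=18,
                label=str(obs),
            )
        ax.axhline(reference_pct, color="red", ls="--", lw=1)
        ax.axhline(-reference_pct, color="red", ls="--", lw=1)
        if lab in loam_by_group:
            ax.axhline(loam_by_group[lab], color="black", lw=1)
            ax.axhline(-loam_by_group[lab], color="black", lw=1)
        ax.set_xscale("log")
        ax.set_xlabel("mean observed volume (mm³)")
        ax.set_ylabel("deviation from subject mean (%)")
        ax.set_title(f"stratum {lab}")
    for ax in axes.ravel()[len(groups):]:
        ax.set_visible(False)
    axes.ravel()[0].legend(fontsize=7, title="observer")
    fig.tight_layout()
    return fig


def plot_window_curve(curve, threshold_pct: float = 20.0, crossing: float | None = None):
    """Sliding-window LOAM% curve with its CI band and the cutoff line."""
    table = curve.table if hasattr(curve, "table") else curve
    fig, ax = plt.subplots(figsize=(6.5, 4.2))
    v = table["mean_volume"]
    ax.plot(v, table["loam_pct"], color="black", lw=1.4, label="LOAM%")
    ax.fill_between(
        v,
        table["loam_pct_ci_low"],
        table["loam_pct_ci_high"],
        color="0.8",
        label="95% CI",
    )
    ax.axhline(threshold_pct, color="red", ls="--", lw=1, label=f"{threshold_pct:g}% limit")
    if crossing is not None:
        ax.axvline(crossing, color="red", ls=":", lw=1)
        ax.annotate(f"{crossing:.0f} mm³", (crossing, threshold_pct), fontsize=8,
                    xytext=(4, 6), textcoords="offset points", color="red")
    ax.set_xscale("log")
    ax.set_xlabel("window mean volume (mm³)")
    ax.set_ylabel("LOAM (% of mean volume)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
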