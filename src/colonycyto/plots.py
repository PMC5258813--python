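"""Figure panels: two-channel dot plots, gated histograms, concordance."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .concordance import ConcordanceResult, MarkerProfile
from .gating import GateSpec, HistogramResult, QuadrantResult

_QUADRANT_COLORS = {
    "double_pos": "tab:red",
    "x_single_pos": "gold",
    "y_single_pos": "tab:green",
    "double_neg": "black",
}


def scatter_quadrants(
    gated: pd.DataFrame,
    result: QuadrantResult,
    x_label: str = "marker_x",
    y_label: str = "marker_y",
    ax=None,
):
    """Bidimensional expression plot, one dot per cell, colored by quadrant,
    annotated with the quadrant percentages."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4))
    gx, gy = result.gate_x, result.gate_y
    x = gated[f"mean_{gx.channel}"].clip(lower=1.0)
    y = gated[f"mean_{gy.channel}"].clip(lower=1.0)
    for qd, color in _QUADRANT_COLORS.items():
        sel = gated["quadrant"] == qd
        ax.scatter(x[sel], y[sel], s=4, c=color, linewidths=0,
                   label=f"{qd} {result.percentages[qd]:.1f}%")
    ax.axvline(max(gx.threshold, 1.0), color="grey", lw=0.8)
    ax.axhline(max(gy.threshold, 1.0), color="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{x_label} mean intensity (counts)")
    ax.set_ylabel(f"{y_label} mean intensity (counts)")
    ax.legend(fontsize=6, loc="upper left")
    return ax


def histogram_panel(hist: HistogramResult, channel_label: str, ax=None):
    """Log-binned expression histogram, positive part red, negative black."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 2.6))
    centers = np.sqrt(hist.bin_edges[:-1] * hist.bin_edges[1:])
    widths = np.diff(hist.bin_edges)
    ax.bar(centers, hist.counts_negative, width=widths, color="black", align="center")
    ax.bar(centers, hist.counts_positive, width=widths,
           bottom=hist.counts_negative, color="tab:red", align="center")
    ax.axvline(max(hist.threshold, hist.bin_edges[0]), color="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel(f"{channel_label} mean intensity (counts)")
    ax.set_ylabel("cells")
    return ax


def concordance_panel(
    imaging: list[MarkerProfile],
    flow: list[MarkerProfile],
    result: ConcordanceResult,
    axes=None,
):
    """Imaging-vs-flow scatter of marker percentages plus per-line
    mean r +/- SE bars."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(8, 3.4))
    ax0, ax1 = axes
    flow_by_key = {(p.line_id, p.replicate_id): p for p in flow}
    lines = sorted({p.line_id for p in imaging})
    cmap = plt.get_cmap("tab10")
    for i, line in enumerate(lines):
        xs, ys = [], []
        for p in imaging:
            if p.line_id != line:
                continue
            f = flow_by_key[(p.line_id, p.replicate_id)]
            for m in sorted(p.percents):
                xs.append(p.percents[m])
                ys.append(f.percents[m])
        ax0.scatter(xs, ys, s=14, color=cmap(i), label=line)
    ax0.plot([0, 100], [0, 100], color="grey", lw=0.8, ls="--")
    ax0.set_xlabel("imaging CM (% positive)")
    ax0.set_ylabel("flow CM (% positive)")
    ax0.legend(fontsize=7)

    per_line = result.per_line
    ax1.bar(per_line["line_id"], per_line["mean_r"],
            yerr=per_line["se"], capsize=3, color="lightsteelblue",
            edgecolor="black")
    for i, row in per_line.iterrows():
        ax1.text(i, 0.05, str(int(row["n_replicates"])), ha="center", fontsize=8)
    ax1.axhline(0.7, color="grey", lw=0.8, ls="--")
    ax1.set_ylim(0, 1.05)
    ax1.set_ylabel("Pearson r (mean ± SE)")
    return axes


def save(fig_or_ax, path, dpi: int = 130) -> None:
    fig = getattr(fig_or_ax, "figure", fig_or_ax)
    if isinstance(fig, np.ndarray):
        fig = fig.flat[0].figure
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
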