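"""Cytometric gating: thresholds, quadrants, percent positive, histograms.

Positivity thresholds come from a negative-control specimen (stained
without primary antibody): the gate is an upper quantile (default 99.5th
percentile, linear-interpolation definition) of the control cells' mean
intensity in that channel.  A cell is positive iff its mean intensity is
*strictly* above the threshold; ties count negative.  Two-channel quadrant
gating assigns each cell exactly one of double-positive, x-single-positive,
y-single-positive or double-negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

QUADRANTS = ("double_pos", "x_single_pos", "y_single_pos", "double_neg")


@dataclass
class GateSpec:
    """A per-channel positivity threshold and its provenance."""

    channel: str
    threshold: float
    q: float = 0.995  # negative-control quantile that set the threshold
    control_n: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GateSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class QuadrantResult:
    """Counts and percentages over the four quadrant classes."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total_n: int
    gate_x: GateSpec
    gate_y: GateSpec


def _column(cells: pd.DataFrame, channel: str) -> np.ndarray:
    col = f"mean_{channel}"
    if col not in cells.columns:
        raise KeyError(f"channel {channel!r} not in cell table (no column {col!r})")
    return cells[col].to_numpy(float)


def fit_threshold(control: pd.DataFrame, channel: str, q: float = 0.995) -> GateSpec:
    """Gate threshold = empirical q-quantile (linear interpolation) of the
    negative-control cells' mean intensity in ``channel``."""
    if not 0.0 < q <= 1.0:
        raise ValueError(f"quantile q must be in (0, 1], got {q}")
    vals = _column(control, channel)
    if vals.size == 0:
        raise ValueError(f"empty negative control for channel {channel!r}")
    thr = float(np.quantile(vals, q, method="linear"))
    return GateSpec(channel=channel, threshold=max(thr, 0.0), q=q,
                    control_n=int(vals.size))


def percent_positive(cells: pd.DataFrame, gate: GateSpec) -> float:
    """100 x fraction of cells strictly above the gate threshold."""
    vals = _column(cells, gate.channel)
    if vals.size == 0:
        raise ValueError("empty cell table")
    return 100.0 * float((vals > gate.threshold).mean())


def classify_quadrants(
    cells: pd.DataFrame, gate_x: GateSpec, gate_y: GateSpec
) -> tuple[QuadrantResult, pd.DataFrame]:
    """Quadrant-gate a cell table on two channels.

    Returns the aggregate :class:`QuadrantResult` and a copy of the table
    with a per-cell ``quadrant`` column (used downstream for spatial
    backtracking and enrichment).
    """
    if cells.empty:
        raise ValueError("empty cell table")
    x = _column(cells, gate_x.channel) > gate_x.threshold
    y = _column(cells, gate_y.channel) > gate_y.threshold
    quadrant = np.where(
        x & y, "double_pos",
        np.where(x & ~y, "x_single_pos", np.where(~x & y, "y_single_pos", "double_neg")),
    )
    out = cells.copy()
    out["quadrant"] = quadrant
    n = len(out)
    counts = {qd: int((quadrant == qd).sum()) for qd in QUADRANTS}
    percentages = {qd: 100.0 * counts[qd] / n for qd in QUADRANTS}
    return (
        QuadrantResult(counts=counts, percentages=percentages, total_n=n,
                       gate_x=gate_x, gate_y=gate_y),
        out,
    )


@dataclass
class HistogramResult:
    """Log-binned expression histogram split at the gate threshold."""

    bin_edges: np.ndarray  # n_bins + 1 edges, log-spaced over [1, ceiling]
    counts: np.ndarray
    counts_positive: np.ndarray
    counts_negative: np.ndarray
    threshold: float


def expression_histogram(
    cells: pd.DataFrame,
    channel: str,
    gate: GateSpec,
    n_bins: int = 64,
    ceiling: float = 4095.0,
) -> HistogramResult:
    """Histogram of per-cell mean intensity on log-spaced bins over
    [1, ceiling], partitioned into positive/negative at the gate.

    Values outside [1, ceiling] are clipped into the end bins so that the
    bin counts always conserve the number of cells.
    """
    if n_bins <= 0:
        raise ValueError(f"n_bins must be positive, got {n_bins}")
    vals = _column(cells, channel)
    if vals.size == 0:
        raise ValueError("empty cell table")
    edges = np.logspace(0.0, np.log10(ceiling), n_bins + 1)
    clipped = np.clip(vals, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    pos = vals > gate.threshold
    cpos, _ = np.histogram(clipped[pos], bins=edges)
    return HistogramResult(
        bin_edges=edges, counts=counts, counts_positive=cpos,
        counts_negative=counts - cpos, threshold=gate.threshold,
    )
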