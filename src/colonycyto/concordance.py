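"""Imaging-vs-flow concordance of percent-positive marker profiles.

Imaging cytometry and flow cytometry read the same specimen through very
different instruments, so individual marker percentages differ; the claim
being tested is that the *profile across markers* agrees.  Concordance is
quantified per replicate as Pearson's r across the marker vector (five
markers in the reference design), then summarized per cell line as
mean +/- SE over independent replicates (SE = sample sd / sqrt(n), n - 1
denominator; a single replicate reports SE = 0 with an explicit flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MarkerProfile:
    """Percent-positive per marker for one (line, replicate, modality)."""

    line_id: str
    replicate_id: int
    modality: str  # "imaging" | "flow"
    percents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in ("imaging", "flow"):
            raise ValueError(f"unknown modality {self.modality!r}")
        for m, p in self.percents.items():
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percent for {m!r} out of [0, 100]: {p}")

    def vector(self, markers: list[str]) -> np.ndarray:
        return np.array([self.percents[m] for m in markers], dtype=float)


@dataclass
class ConcordanceResult:
    """Per-replicate r values and the per-line mean +/- SE summary."""

    per_replicate: pd.DataFrame  # line_id, replicate_id, r, n_markers
    per_line: pd.DataFrame  # line_id, mean_r, se, n_replicates, single_replicate
    pooled: bool = False

    @property
    def min_line_mean_r(self) -> float:
        return float(self.per_line["mean_r"].min())


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length (>= 3) vectors.

    Constant input makes the correlation undefined and is an error rather
    than a NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def concordance_summary(
    imaging: list[MarkerProfile],
    flow: list[MarkerProfile],
    pool_replicates: bool = False,
) -> ConcordanceResult:
    """Match imaging/flow profiles on (line, replicate) and summarize.

    Default: one r per replicate across its marker vector, then per-line
    mean and SE over replicates.  ``pool_replicates=True`` instead pools
    all (marker, replicate) points of a line into a single correlation
    (SE reported as 0, n_replicates = pooled replicate count).
    """
    key = lambda p: (p.line_id, p.replicate_id)
    flow_by_key = {key(p): p for p in flow}
    rows = []
    for img in imaging:
        k = key(img)
        if k not in flow_by_key:
            raise ValueError(f"no flow profile for line/replicate {k}")
        flw = flow_by_key[k]
        if set(img.percents) != set(flw.percents):
            raise ValueError(
                f"marker-set mismatch for {k}: "
                f"{sorted(img.percents)} vs {sorted(flw.percents)}"
            )
        markers = sorted(img.percents)
        rows.append(
            {
                "line_id": img.line_id,
                "replicate_id": img.replicate_id,
                "r": pearson_r(img.vector(markers), flw.vector(markers)),
                "n_markers": len(markers),
                "_img": img.vector(markers),
                "_flw": flw.vector(markers),
            }
        )
    if not rows:
        raise ValueError("no matched profiles")
    per_rep = pd.DataFrame(rows)

    line_rows = []
    for line, grp in per_rep.groupby("line_id", sort=True):
        if pool_replicates:
            x = np.concatenate(list(grp["_img"]))
            y = np.concatenate(list(grp["_flw"]))
            line_rows.append(
                {"line_id": line, "mean_r": pearson_r(x, y), "se": 0.0,
                 "n_replicates": len(grp), "single_replicate": len(grp) == 1}
            )
        else:
            rs = grp["r"].to_numpy()
            se = float(rs.std(ddof=1) / np.sqrt(rs.size)) if rs.size > 1 else 0.0
            line_rows.append(
                {"line_id": line, "mean_r": float(rs.mean()), "se": se,
                 "n_replicates": rs.size, "single_replicate": rs.size == 1}
            )
    per_line = pd.DataFrame(line_rows)
    per_rep = per_rep.drop(columns=["_img", "_flw"])
    return ConcordanceResult(per_replicate=per_rep, per_line=per_line,
                             pooled=pool_replicates)


def profiles_from_csv(path, modality: str) -> list[MarkerProfile]:
    """Read profiles from a long CSV with columns
    ``line_id, replicate_id, marker, percent``."""
    df = pd.read_csv(path)
    out = []
    for (line, rep), grp in df.groupby(["line_id", "replicate_id"], sort=True):
        out.append(
            MarkerProfile(
                line_id=str(line), replicate_id=int(rep), modality=modality,
                percents=dict(zip(grp["marker"], grp["percent"].astype(float))),
            )
        )
    return out


def profiles_to_csv(profiles: list[MarkerProfile], path) -> None:
    rows = [
        {"line_id": p.line_id, "replicate_id": p.replicate_id,
         "modality": p.modality, "marker": m, "percent": v}
        for p in profiles
        for m, v in sorted(p.percents.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
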