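"""Simulated replications of the paired imaging/flow study design.

The reference design characterizes four hPSC lines (201B7, 253G1, Tic,
H9); for each line and replicate, sister cultures are read in parallel by
imaging cytometry (four stained fields, OCT-3/4 paired with one of SSEA3,
SSEA4, TRA-1-60, SSEA1, plus one negative-control field) and by flow
cytometry (dissociated readings of the same latent populations, with a
dissociated negative control).  Each replicate yields a five-marker
percent-positive profile per modality; concordance is Pearson's r across
the profile, summarized per line over replicates.

A replicate's four stained fields total roughly 2000–2500 cells with the
default generator configuration.  Seeds are derived deterministically from
a single experiment seed via ``numpy`` seed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import gating
from .concordance import ConcordanceResult, MarkerProfile, concordance_summary
from .quantify import measure_cells
from .segmentation import SegmentationParams, segment_nuclei
from .simulate import (
    LINE_PROFILES,
    SimConfig,
    generate_colony_field,
    generate_ground_truth,
    simulate_flow_readings,
)

SURFACE_MARKERS = ("SSEA3", "SSEA4", "TRA-1-60", "SSEA1")
OCT4 = "OCT-3/4"


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class ImagingMeasurement:
    """Imaging-chain result for one stained field."""

    percent_x: float  # OCT-3/4 percent positive
    percent_y: float  # surface-marker percent positive
    n_cells: int
    cells: pd.DataFrame  # gated cell table (with quadrant column)


def imaging_percent_positive(
    config: SimConfig,
    control_cells: pd.DataFrame,
    seg: Optional[SegmentationParams] = None,
    q: float = 0.995,
) -> ImagingMeasurement:
    """Run the imaging chain on one simulated field.

    Generate → segment the nuclear channel → measure all channels over the
    nucleus areas → gate both marker channels with thresholds fitted on the
    matched negative-control cell table.
    """
    seg = seg or SegmentationParams()
    image, _truth = generate_colony_field(config)
    labels = segment_nuclei(image.channel("nuclear"), seg)
    cells = measure_cells(labels, image)
    if cells.empty:
        raise ValueError("imaging chain found no cells")
    gate_x = gating.fit_threshold(control_cells, "marker_x", q)
    gate_y = gating.fit_threshold(control_cells, "marker_y", q)
    _, gated = gating.classify_quadrants(cells, gate_x, gate_y)
    return ImagingMeasurement(
        percent_x=gating.percent_positive(cells, gate_x),
        percent_y=gating.percent_positive(cells, gate_y),
        n_cells=len(cells),
        cells=gated,
    )


def flow_percent_positive(
    config: SimConfig, control_values: dict[str, np.ndarray], q: float = 0.995
) -> tuple[float, float, int]:
    """Flow arm for one stained population: simulate a sister specimen of
    the same population (its latent state only — no imaging), dissociate
    and read it, and gate against the dissociated negative control's
    quantile thresholds."""
    truth = generate_ground_truth(config)
    sample = simulate_flow_readings(truth, config)
    out = []
    for ch in ("marker_x", "marker_y"):
        thr = float(np.quantile(control_values[ch], q, method="linear"))
        out.append(100.0 * float((sample.readings[ch].to_numpy() > thr).mean()))
    return out[0], out[1], truth.n_cells


def run_replicate(
    line_id: str,
    marginals: dict[str, float],
    base_config: SimConfig,
    seg: SegmentationParams,
    q: float,
    ss: np.random.SeedSequence,
) -> tuple[MarkerProfile, MarkerProfile, int]:
    """One replicate of one line: four stained fields plus one shared
    negative-control field per modality (sister cultures — the imaging and
    flow specimens are independent draws from the same population),
    returning the (imaging, flow) five-marker profiles."""
    children = ss.spawn(2 * len(SURFACE_MARKERS) + 2)
    img_children = children[: len(SURFACE_MARKERS)]
    flow_children = children[len(SURFACE_MARKERS) : 2 * len(SURFACE_MARKERS)]
    ctrl_img_child, ctrl_flow_child = children[-2:]

    # shared negative controls for the replicate (one control well per plate)
    ctrl_cfg = replace(
        base_config, seed=_child_seed(ctrl_img_child)
    ).negative_control(seed_offset=0)
    ctrl_img, _ = generate_colony_field(ctrl_cfg)
    ctrl_labels = segment_nuclei(ctrl_img.channel("nuclear"), seg)
    ctrl_cells = measure_cells(ctrl_labels, ctrl_img)
    ctrl_flow_cfg = replace(ctrl_cfg, seed=_child_seed(ctrl_flow_child))
    ctrl_truth = generate_ground_truth(ctrl_flow_cfg)
    ctrl_flow = simulate_flow_readings(ctrl_truth, ctrl_flow_cfg)
    ctrl_flow_values = {
        ch: ctrl_flow.readings[ch].to_numpy() for ch in ("marker_x", "marker_y")
    }

    img_pct: dict[str, float] = {}
    flw_pct: dict[str, float] = {}
    oct4_img, oct4_flw = [], []
    total_cells = 0
    p_x = marginals[OCT4] / 100.0
    for marker, img_child, flow_child in zip(SURFACE_MARKERS, img_children, flow_children):
        cfg = SimConfig.for_marker_pair(
            p_x,
            marginals[marker] / 100.0,
            marker_y_name=marker,
            seed=_child_seed(img_child),
            field_shape=base_config.field_shape,
            n_colonies=base_config.n_colonies,
            colony_radius_range=base_config.colony_radius_range,
            nucleus_radius_mean=base_config.nucleus_radius_mean,
            nucleus_radius_sd=base_config.nucleus_radius_sd,
            packing_min_spacing=base_config.packing_min_spacing,
            cells_per_colony=base_config.cells_per_colony,
            n_delaminated=base_config.n_delaminated,
            edge_bias=base_config.edge_bias,
            background_level=base_config.background_level,
            background_noise_sd=base_config.background_noise_sd,
            camera_bit_depth=base_config.camera_bit_depth,
            camera_gain=base_config.camera_gain,
            flow_decades=base_config.flow_decades,
            flow_cv=base_config.flow_cv,
        )
        meas = imaging_percent_positive(cfg, ctrl_cells, seg, q)
        img_pct[marker] = meas.percent_y
        oct4_img.append(meas.percent_x)
        total_cells += meas.n_cells
        flow_cfg = replace(cfg, seed=_child_seed(flow_child))
        fx, fy, _n = flow_percent_positive(flow_cfg, ctrl_flow_values, q)
        flw_pct[marker] = fy
        oct4_flw.append(fx)
    img_pct[OCT4] = float(np.mean(oct4_img))
    flw_pct[OCT4] = float(np.mean(oct4_flw))
    rep_id = 0  # caller overwrites
    return (
        MarkerProfile(line_id, rep_id, "imaging", img_pct),
        MarkerProfile(line_id, rep_id, "flow", flw_pct),
        total_cells,
    )


@dataclass
class ExperimentResult:
    imaging: list[MarkerProfile]
    flow: list[MarkerProfile]
    concordance: ConcordanceResult
    total_cells: int


def run_concordance_experiment(
    lines: Optional[dict[str, dict[str, float]]] = None,
    n_replicates: int = 3,
    base_config: Optional[SimConfig] = None,
    seg: Optional[SegmentationParams] = None,
    q: float = 0.995,
    seed: int = 1,
    pool_replicates: bool = False,
) -> ExperimentResult:
    """Full simulated replication of the four-line paired design.

    Defaults: the four line profiles of :data:`~colonycyto.simulate.LINE_PROFILES`,
    three replicates per line, default generator and segmentation settings
    (~2000+ cells per replicate across its four stained fields).
    """
    lines = lines or LINE_PROFILES
    base_config = base_config or SimConfig()
    seg = seg or SegmentationParams()
    root = np.random.SeedSequence(seed)
    line_seeds = root.spawn(len(lines))
    imaging, flow = [], []
    total = 0
    for (line_id, marginals), line_ss in zip(sorted(lines.items()), line_seeds):
        for rep, rep_ss in enumerate(line_ss.spawn(n_replicates), start=1):
            img, flw, n = run_replicate(line_id, marginals, base_config, seg, q, rep_ss)
            img.replicate_id = rep
            flw.replicate_id = rep
            imaging.append(img)
            flow.append(flw)
            total += n
    result = concordance_summary(imaging, flow, pool_replicates=pool_replicates)
    return ExperimentResult(
        imaging=imaging, flow=flow, concordance=result, total_cells=total
    )


def estimate_marginal_recovery(
    fraction: float,
    marker: str = "SSEA1",
    min_cells: int = 2000,
    seed: int = 0,
    seg: Optional[SegmentationParams] = None,
    q: float = 0.995,
    base_config: Optional[SimConfig] = None,
) -> tuple[float, int]:
    """Recover a known marginal positive fraction through the full imaging
    chain, pooling fields until at least ``min_cells`` cells are measured.

    Returns (estimated percent positive, n cells).  ``fraction`` is the
    ground-truth marginal in percent.
    """
    seg = seg or SegmentationParams()
    base = base_config or SimConfig()
    ss = np.random.SeedSequence(seed)
    ctrl_ss, *field_ss = ss.spawn(21)
    ctrl_cfg = replace(base, seed=_child_seed(ctrl_ss)).negative_control(seed_offset=0)
    ctrl_img, _ = generate_colony_field(ctrl_cfg)
    ctrl_cells = measure_cells(
        segment_nuclei(ctrl_img.channel("nuclear"), seg), ctrl_img
    )
    gate = gating.fit_threshold(ctrl_cells, "marker_y", q)
    n_pos = 0
    n_tot = 0
    for child in field_ss:
        cfg = SimConfig.for_marker_pair(
            0.852, fraction / 100.0, marker_y_name=marker, seed=_child_seed(child)
        )
        image, _ = generate_colony_field(cfg)
        cells = measure_cells(segment_nuclei(image.channel("nuclear"), seg), image)
        vals = cells["mean_marker_y"].to_numpy(float)
        n_pos += int((vals > gate.threshold).sum())
        n_tot += len(cells)
        if n_tot >= min_cells:
            break
    if n_tot == 0:
        raise ValueError("no cells recovered")
    return 100.0 * n_pos / n_tot, n_tot
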