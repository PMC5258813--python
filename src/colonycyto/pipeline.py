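"""End-to-end orchestration: simulate → segment → measure → gate → flow →
concordance → spatial, with every intermediate persisted and a manifest
recording config, seeds and output checksums.

Rerunning with an identical config reproduces bit-identical images, CSVs
and checksums (figure files are listed in the manifest but not checksummed;
they are presentation artifacts).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, gating, plots, spatial
from .concordance import profiles_to_csv
from .core import ImageField, write_labels
from .experiment import run_concordance_experiment
from .quantify import measure_cells, provenance_hash
from .segmentation import SegmentationParams, segment_nuclei
from .simulate import (
    LINE_PROFILES,
    SimConfig,
    generate_ground_truth,
    simulate_flow_readings,
)

logger = logging.getLogger("colonycyto")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    The global ``seed`` propagates to every stochastic stage: it overrides
    ``sim.seed``, seeds the sister flow specimen and the permutation test.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    gating_q: float = 0.995
    #: single-linkage distance as a multiple of the median nucleus diameter
    linkage_factor: float = 3.0
    min_colony_size: int = 5
    edge_band: Optional[float] = None  # pixels; None = 1.5 x median diameter
    n_permutations: int = 1999
    pool_replicates: bool = False
    run_concordance: bool = True
    concordance_lines: tuple[str, ...] = ("201B7",)
    concordance_replicates: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["concordance_lines"] = list(self.concordance_lines)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["sim"] = SimConfig.from_dict(d["sim"])
        d["seg"] = SegmentationParams(**d["seg"])
        d["concordance_lines"] = tuple(d.get("concordance_lines", ("201B7",)))
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, persist all artifacts under ``outdir`` and
    return (and write) the run manifest.

    Any stage failure aborts with a :class:`RuntimeError` naming the stage.
    A run with no cells (e.g. ``n_colonies = 0`` and no delaminated cells)
    completes, reporting ``"no cells"`` and skipping the gated stages.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = replace(config.sim, seed=config.seed)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
        "figures": [],
        "warnings": [],
        "timings_s": {},
        "report": {},
    }
    report = manifest["report"]

    def _record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                logger.info("stage %s ...", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["timings_s"][name] = round(
                    time.perf_counter() - self_inner.t0, 3
                )
                if exc is not None:
                    raise RuntimeError(
                        f"pipeline stage {name!r} failed: {exc}"
                    ) from exc
                return False

        return _Ctx()

    config.to_yaml(outdir / "pipeline_config.yaml")
    _record("pipeline_config", outdir / "pipeline_config.yaml")

    with _stage("simulate"):
        from .simulate import generate_colony_field

        image, truth = generate_colony_field(sim)
        image.to_tiff(outdir / "field.tif")
        truth.to_csv(outdir / "truth.csv")
        ctrl_cfg = sim.negative_control()
        ctrl_image, _ctrl_truth = generate_colony_field(ctrl_cfg)
        ctrl_image.to_tiff(outdir / "control_field.tif")
        _record("field", outdir / "field.tif")
        _record("truth", outdir / "truth.csv")
        _record("control_field", outdir / "control_field.tif")
        report["n_cells_truth"] = truth.n_cells

    with _stage("segment"):
        labels = segment_nuclei(image.channel("nuclear"), config.seg)
        ctrl_labels = segment_nuclei(ctrl_image.channel("nuclear"), config.seg)
        write_labels(outdir / "labels.tif", labels)
        write_labels(outdir / "control_labels.tif", ctrl_labels)
        _record("labels", outdir / "labels.tif")
        _record("control_labels", outdir / "control_labels.tif")
        report["n_cells_segmented"] = int(labels.max())

    with _stage("measure"):
        cells = measure_cells(labels, image)
        cells.attrs["provenance"] = provenance_hash(
            sim.to_dict(), asdict(config.seg)
        )
        ctrl_cells = measure_cells(ctrl_labels, ctrl_image)
        cells.to_csv(outdir / "cells.csv", index=False)
        ctrl_cells.to_csv(outdir / "control_cells.csv", index=False)
        _record("cells", outdir / "cells.csv")
        _record("control_cells", outdir / "control_cells.csv")

    if cells.empty:
        report["status"] = "no cells"
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        logger.info("pipeline finished: no cells")
        return manifest
    report["status"] = "ok"

    with _stage("gate"):
        gate_x = gating.fit_threshold(ctrl_cells, "marker_x", config.gating_q)
        gate_y = gating.fit_threshold(ctrl_cells, "marker_y", config.gating_q)
        gate_x.to_json(outdir / "gate_x.json")
        gate_y.to_json(outdir / "gate_y.json")
        quad, gated = gating.classify_quadrants(cells, gate_x, gate_y)
        gated.to_csv(outdir / "cells_gated.csv", index=False)
        pd.DataFrame(
            [
                {"quadrant": qd, "count": quad.counts[qd],
                 "percent": quad.percentages[qd]}
                for qd in gating.QUADRANTS
            ]
        ).to_csv(outdir / "quadrants.csv", index=False)
        for name in ("gate_x", "gate_y", "cells_gated", "quadrants"):
            _record(name, outdir / f"{name}.{'json' if name.startswith('gate') else 'csv'}")
        report["quadrant_percentages"] = quad.percentages
        report["percent_positive"] = {
            sim.marker_x_name: gating.percent_positive(cells, gate_x),
            sim.marker_y_name: gating.percent_positive(cells, gate_y),
        }
        ax = plots.scatter_quadrants(gated, quad, sim.marker_x_name, sim.marker_y_name)
        plots.save(ax, outdir / "fig_quadrants.png")
        hist = gating.expression_histogram(
            cells, "marker_y", gate_y, ceiling=float(sim.camera_ceiling)
        )
        plots.save(
            plots.histogram_panel(hist, sim.marker_y_name),
            outdir / "fig_histogram.png",
        )
        manifest["figures"] += ["fig_quadrants.png", "fig_histogram.png"]

    with _stage("flow"):
        flow_cfg = replace(sim, seed=(config.seed * 2654435761 + 101) % 2**31)
        flow_truth = generate_ground_truth(flow_cfg)
        sample = simulate_flow_readings(flow_truth, flow_cfg)
        sample.to_csv(outdir / "flow.csv")
        ctrl_flow_cfg = replace(
            ctrl_cfg, seed=(config.seed * 2654435761 + 103) % 2**31
        )
        ctrl_flow = simulate_flow_readings(
            generate_ground_truth(ctrl_flow_cfg), ctrl_flow_cfg
        )
        flow_pct = {}
        for ch, marker in (("marker_x", sim.marker_x_name),
                           ("marker_y", sim.marker_y_name)):
            thr = float(
                np.quantile(ctrl_flow.readings[ch], config.gating_q, method="linear")
            )
            flow_pct[marker] = 100.0 * float(
                (sample.readings[ch].to_numpy() > thr).mean()
            )
        _record("flow", outdir / "flow.csv")
        report["flow_percent_positive"] = flow_pct

    if config.run_concordance:
        with _stage("concordance"):
            lines = {k: LINE_PROFILES[k] for k in config.concordance_lines}
            exp = run_concordance_experiment(
                lines=lines,
                n_replicates=config.concordance_replicates,
                seg=config.seg,
                q=config.gating_q,
                seed=config.seed + 1,
                pool_replicates=config.pool_replicates,
            )
            profiles_to_csv(exp.imaging, outdir / "profiles_imaging.csv")
            profiles_to_csv(exp.flow, outdir / "profiles_flow.csv")
            exp.concordance.per_replicate.to_csv(
                outdir / "concordance_replicates.csv", index=False
            )
            exp.concordance.per_line.to_csv(
                outdir / "concordance_lines.csv", index=False
            )
            for name in ("profiles_imaging", "profiles_flow",
                         "concordance_replicates", "concordance_lines"):
                _record(name, outdir / f"{name}.csv")
            report["concordance_mean_r"] = {
                row["line_id"]: row["mean_r"]
                for _, row in exp.concordance.per_line.iterrows()
            }
            plots.save(
                plots.concordance_panel(exp.imaging, exp.flow, exp.concordance),
                outdir / "fig_concordance.png",
            )
            manifest["figures"].append("fig_concordance.png")

    with _stage("spatial"):
        med_diam = 2.0 * float(
            np.median(np.sqrt(cells["area"].to_numpy(float) / np.pi))
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assignment = spatial.assign_colonies(
                gated,
                linkage_distance=config.linkage_factor * med_diam,
                min_colony_size=config.min_colony_size,
                labels=labels,
                field_shape=labels.shape,
            )
            scores = spatial.edge_scores(assignment, gated, config.edge_band)
        manifest["warnings"] += [str(w.message) for w in caught]
        assignment.colonies.to_csv(outdir / "colonies.csv", index=False)
        cells_spatial = gated.merge(
            scores[["cell_id", "colony_id", "boundary_distance",
                    "normalized_score", "edge_flag"]],
            on="cell_id",
        )
        cells_spatial.to_csv(outdir / "cells_spatial.csv", index=False)
        _record("colonies", outdir / "colonies.csv")
        _record("cells_spatial", outdir / "cells_spatial.csv")
        phenotype = sim.edge_phenotype
        in_colony = cells_spatial[cells_spatial["colony_id"] > 0]
        if len(in_colony) >= 10 and (in_colony["quadrant"] == phenotype).any():
            enr = spatial.phenotype_edge_enrichment(
                cells_spatial, phenotype,
                n_permutations=config.n_permutations,
                seed=config.seed + 7,
            )
            enr_dict = {
                "phenotype": enr.phenotype,
                "statistic": enr.statistic,
                "p_value": enr.p_value,
                "n_cells": enr.n_cells,
                "n_phenotype": enr.n_phenotype,
                "n_permutations": enr.n_permutations,
            }
        else:
            enr_dict = {"phenotype": phenotype, "statistic": None,
                        "p_value": None, "note": "too few in-colony phenotype cells"}
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(enr_dict, fh, indent=1, sort_keys=True)
        _record("enrichment", outdir / "enrichment.json")
        report["edge_enrichment"] = enr_dict

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _record("report", outdir / "report.json")

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline finished: %d cells", len(cells))
    return manifest
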