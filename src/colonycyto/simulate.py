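"""Synthetic colony-image and flow-cytometry simulator with ground truth.

Human pluripotent stem cells (hPSCs) grow as flat monolayer colonies of
tightly packed cells with large nuclei and scant cytoplasm.  Cultures are
typically in a *quasi-undifferentiated* state: mostly undifferentiated cells
(OCT-3/4+, SSEA3+, SSEA4+, TRA-1-60+) mixed with spontaneously
differentiated cells (SSEA1+) that concentrate at, or delaminate from,
colony peripheries.  This module renders such specimens as multi-channel
camera images with fully known per-cell ground truth, and simulates paired
flow-cytometry readings of the same latent population, so that every stage
of the imaging-cytometry pipeline can be validated end to end.

Model summary
-------------
* Colony footprints are star-convex radial blobs
  ``r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k))`` with low-order
  harmonics and total perturbation amplitude <= 0.3.
* Nuclei are placed inside footprints by minimum-spacing rejection sampling
  (plus a configurable count of delaminated cells outside all colonies).
* Each cell carries a phenotype from the quadrant classes
  ``double_pos / x_single_pos / y_single_pos / double_neg`` (x = the
  transcription factor channel, y = the surface-marker channel).  The
  edge-biased class is allocated to cells with probability proportional to
  ``exp(-edge_bias * d)`` where ``d`` in [0, 1] is the normalized distance
  from the colony boundary, renormalized so that marginal class fractions
  are preserved.
* True expression per channel is lognormal, with parameters keyed by
  (phenotype, channel).
* The camera integrates per-nucleus intensity kernels (Gaussian-profile
  discs, hard support at twice the nucleus radius) plus Gaussian background
  noise, then quantizes to integer counts clipped at ``2**bit_depth - 1``
  (4096 levels for the default 12-bit camera).  Surface markers are rendered
  over a slightly wider footprint than the nucleus (nucleus + annulus),
  the transcription factor over the nucleus only.
* Flow readings multiply true expression by mean-1 lognormal noise with the
  configured coefficient of variation and clip to ``10**flow_decades``
  (10,000 for the default 4-decade instrument); cell order is shuffled
  because dissociation destroys spatial information.

All randomness flows through a single generator seeded from
:attr:`SimConfig.seed`; draws occur in a fixed documented order, so an
identical config yields bit-identical images and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import CHANNELS, ImageField

#: Quadrant phenotype classes; x = marker_x positive, y = marker_y positive.
PHENOTYPES: tuple[str, ...] = (
    "double_pos",
    "x_single_pos",
    "y_single_pos",
    "double_neg",
)

#: Which phenotypes are positive on which marker channel.
POSITIVE_ON = {
    "marker_x": ("double_pos", "x_single_pos"),
    "marker_y": ("double_pos", "y_single_pos"),
}

# Default lognormal (mu, sigma) of true expression, arbitrary units.
# "neg" doubles as the negative-control level (staining without primary
# antibody leaves only background-level signal).
_POS = (math.log(420.0), 0.7)
_NEG = (math.log(8.0), 0.6)
_NUC = (math.log(1400.0), 0.15)  # nuclear-stain kernel amplitude, counts


def default_expression_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-(phenotype, channel) lognormal (mu, sigma) defaults."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for ph in PHENOTYPES:
        out[ph] = {
            "nuclear": _NUC,
            "marker_x": _POS if ph in POSITIVE_ON["marker_x"] else _NEG,
            "marker_y": _POS if ph in POSITIVE_ON["marker_y"] else _NEG,
        }
    return out


def fractions_from_marginals(
    p_x: float, p_y: float, association: float = 0.0
) -> dict[str, float]:
    """Quadrant-class fractions with given marginal positive fractions.

    ``association`` in [-1, 1] moves the joint away from independence while
    preserving both marginals exactly: +1 is the maximal positive coupling
    (x+ and y+ co-occur as much as the marginals allow), -1 the maximal
    negative coupling.

    Parameters are probabilities in [0, 1], not percents.
    """
    if not (0.0 <= p_x <= 1.0 and 0.0 <= p_y <= 1.0):
        raise ValueError("marginals must lie in [0, 1]")
    if not -1.0 <= association <= 1.0:
        raise ValueError("association must lie in [-1, 1]")
    if association >= 0:
        c = association * min(p_x * (1 - p_y), (1 - p_x) * p_y)
    else:
        c = association * min(p_x * p_y, (1 - p_x) * (1 - p_y))
    return {
        "double_pos": p_x * p_y + c,
        "x_single_pos": p_x * (1 - p_y) - c,
        "y_single_pos": (1 - p_x) * p_y - c,
        "double_neg": (1 - p_x) * (1 - p_y) + c,
    }


#: Marginal percent-positive profiles of the four hPSC lines the simulator
#: emulates: the marker profile of a quasi-undifferentiated culture of each
#: line.  The 201B7 profile is the realistic anchor of the set; 253G1, Tic
#: and H9 carry synthetic but biologically plausible profiles.
LINE_PROFILES: dict[str, dict[str, float]] = {
    "201B7": {"OCT-3/4": 85.2, "SSEA3": 94.0, "SSEA4": 95.0, "TRA-1-60": 87.0, "SSEA1": 30.2},
    "253G1": {"OCT-3/4": 90.0, "SSEA3": 95.5, "SSEA4": 96.0, "TRA-1-60": 91.0, "SSEA1": 18.0},
    "Tic": {"OCT-3/4": 76.0, "SSEA3": 88.0, "SSEA4": 90.5, "TRA-1-60": 81.0, "SSEA1": 41.0},
    "H9": {"OCT-3/4": 93.0, "SSEA3": 96.5, "SSEA4": 97.0, "TRA-1-60": 92.0, "SSEA1": 12.0},
}

#: Surface markers of the undifferentiated state; SSEA1 marks early
#: differentiation, so its positive cells (not its negatives) are the
#: edge-biased differentiated class.
UNDIFF_MARKERS = ("SSEA3", "SSEA4", "TRA-1-60")


class PackingError(RuntimeError):
    """Raised when nuclei or colonies cannot be placed at the requested
    density under the minimum-spacing constraint."""


@dataclass
class SimConfig:
    """Full parameterization of one synthetic field.

    Distances are pixels, intensities camera counts unless noted.  The
    defaults describe a 512x512 field holding three irregular colonies of
    tightly packed nuclei (~600 cells) in the quasi-undifferentiated
    mixture of the 201B7 OCT-3/4 x SSEA1 pairing.
    """

    field_shape: tuple[int, int] = (700, 700)
    n_colonies: int = 4
    colony_radius_range: tuple[float, float] = (75.0, 105.0)
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 0.7
    #: Minimum centre separation of nuclei i, j as a fraction of
    #: ``radius_i + radius_j`` (i.e. of the mean nucleus diameter).
    packing_min_spacing: float = 0.95
    #: Requested nuclei per colony; None packs each colony to saturation.
    cells_per_colony: Optional[int] = None
    #: Differentiated cells scattered outside all colony footprints.
    n_delaminated: int = 20
    phenotype_fractions: dict[str, float] = field(
        default_factory=lambda: fractions_from_marginals(0.852, 0.302, -0.5)
    )
    #: Strength of the peripheral concentration of ``edge_phenotype``.
    edge_bias: float = 3.0
    #: Quadrant class concentrated at colony edges (the differentiated
    #: class of the current marker pairing).
    edge_phenotype: str = "y_single_pos"
    expression_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_expression_params
    )
    background_level: float = 100.0
    background_noise_sd: float = 5.0
    camera_bit_depth: int = 12
    #: Counts per unit true expression at the kernel peak.
    camera_gain: float = 1.0
    flow_decades: int = 4
    flow_cv: float = 0.25
    seed: int = 0
    marker_x_name: str = "OCT-3/4"
    marker_y_name: str = "SSEA1"

    # ---- derived quantities ---------------------------------------------
    @property
    def camera_ceiling(self) -> int:
        """Quantization ceiling: ``2**bit_depth - 1`` (4095 at 12 bit,
        i.e. 4096 levels)."""
        return 2**self.camera_bit_depth - 1

    @property
    def flow_ceiling(self) -> float:
        """Flow clip ceiling ``10**flow_decades`` (default 10,000)."""
        return 10.0**self.flow_decades

    def validate(self) -> None:
        rows, cols = self.field_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"zero-area field: shape {self.field_shape}")
        if self.n_colonies < 0 or self.n_delaminated < 0:
            raise ValueError("counts must be non-negative")
        fr = self.phenotype_fractions
        if set(fr) != set(PHENOTYPES):
            raise ValueError(f"phenotype_fractions must cover {PHENOTYPES}")
        vals = np.array([fr[p] for p in PHENOTYPES], dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("phenotype fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"phenotype fractions sum to {vals.sum()}, not 1")
        if self.edge_phenotype not in PHENOTYPES:
            raise ValueError(f"unknown edge_phenotype {self.edge_phenotype!r}")
        if self.edge_bias < 0:
            raise ValueError("edge_bias must be >= 0")
        if not 0 < self.packing_min_spacing:
            raise ValueError("packing_min_spacing must be positive")
        lo, hi = self.colony_radius_range
        if not 0 < lo <= hi:
            raise ValueError("colony_radius_range must be 0 < lo <= hi")
        if self.camera_bit_depth <= 0 or self.flow_decades <= 0:
            raise ValueError("bit depth and flow decades must be positive")

    # ---- convenience constructors ---------------------------------------
    def negative_control(self, seed_offset: int = 1000) -> "SimConfig":
        """Config for the matched negative-control well: same specimen
        statistics, but every phenotype expresses only background-level
        signal on both marker channels (no primary antibody)."""
        params = {
            ph: {
                "nuclear": self.expression_params[ph]["nuclear"],
                "marker_x": _NEG,
                "marker_y": _NEG,
            }
            for ph in PHENOTYPES
        }
        return replace(
            self, expression_params=params, seed=(self.seed + seed_offset) % 2**31
        )

    @classmethod
    def for_marker_pair(
        cls,
        p_x: float,
        p_y: float,
        marker_y_name: str = "SSEA1",
        seed: int = 0,
        association: Optional[float] = None,
        **kwargs,
    ) -> "SimConfig":
        """Config for one OCT-3/4 x surface-marker staining.

        ``p_x``/``p_y`` are marginal positive fractions in [0, 1].  For
        undifferentiated-state surface markers the double negatives are the
        (edge-biased) differentiated class and positivity couples positively
        with OCT-3/4; for SSEA1 the positives are differentiated and the
        coupling is negative.
        """
        undiff = marker_y_name in UNDIFF_MARKERS
        if association is None:
            association = 0.5 if undiff else -0.5
        return cls(
            phenotype_fractions=fractions_from_marginals(p_x, p_y, association),
            edge_phenotype="double_neg" if undiff else "y_single_pos",
            marker_y_name=marker_y_name,
            seed=seed,
            **kwargs,
        )

    # ---- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
        }
        d["field_shape"] = list(self.field_shape)
        d["colony_radius_range"] = list(self.colony_radius_range)
        d["expression_params"] = {
            ph: {ch: list(p) for ch, p in chans.items()}
            for ph, chans in self.expression_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["field_shape"] = tuple(d["field_shape"])
        d["colony_radius_range"] = tuple(d["colony_radius_range"])
        d["expression_params"] = {
            ph: {ch: tuple(p) for ch, p in chans.items()}
            for ph, chans in d["expression_params"].items()
        }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "cell_id",
    "row",
    "col",
    "radius",
    "colony_id",
    "boundary_dist_norm",
    "phenotype",
    "expr_nuclear",
    "expr_marker_x",
    "expr_marker_y",
]


@dataclass
class GroundTruth:
    """Latent per-cell state of a simulated field.

    ``cells`` has one row per cell with columns :data:`TRUTH_COLUMNS`:
    dense ids 1..n, true centroid (row, col), nucleus radius, colony id
    (0 = delaminated, outside every colony), normalized distance from the
    colony boundary (0 = on the boundary, 1 = deepest point; 0 for
    delaminated cells), quadrant phenotype and true expression per channel
    in pre-instrument arbitrary units.
    """

    cells: pd.DataFrame
    colonies: pd.DataFrame  # colony_id, row, col, radius (base radius R)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def marginal_positive(self, channel: str) -> float:
        """Ground-truth positive fraction on ``marker_x``/``marker_y``."""
        if self.n_cells == 0:
            raise ValueError("empty ground truth")
        return float(self.cells["phenotype"].isin(POSITIVE_ON[channel]).mean())

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        cells = pd.read_csv(path)
        return cls(cells=cells, colonies=pd.DataFrame(columns=["colony_id", "row", "col", "radius"]))


@dataclass
class FlowSample:
    """Simulated dissociated flow-cytometry readings.

    One row per cell: ``cell_id`` (link back to the ground truth — the
    real instrument has no such link; it exists purely for validation) and
    measured ``marker_x``/``marker_y`` intensities clipped to the flow
    dynamic range.
    """

    readings: pd.DataFrame
    flow_ceiling: float

    def to_csv(self, path) -> None:
        self.readings.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------


class _ColonyShape:
    """Star-convex radial blob r(theta) = R * (1 + sum a_k cos(k t + p_k))."""

    def __init__(self, center: tuple[float, float], R: float, rng: np.random.Generator):
        self.center = center
        self.R = R
        ks = np.array([2, 3, 4, 5])
        # total perturbation bounded by 0.3 of R
        amps = rng.uniform(0.0, 1.0, size=ks.size)
        amps *= rng.uniform(0.1, 0.3) / max(amps.sum(), 1e-12)
        self.ks = ks
        self.amps = amps
        self.phases = rng.uniform(0, 2 * np.pi, size=ks.size)

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        pert = sum(
            a * np.cos(k * theta + p)
            for a, k, p in zip(self.amps, self.ks, self.phases)
        )
        return self.R * (1.0 + pert)

    def boundary_radius(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        theta = np.arctan2(rows - self.center[0], cols - self.center[1])
        return self.radius_at(theta)

    def contains(self, rows, cols, margin: float = 0.0) -> np.ndarray:
        rows = np.atleast_1d(np.asarray(rows, dtype=float))
        cols = np.atleast_1d(np.asarray(cols, dtype=float))
        rho = np.hypot(rows - self.center[0], cols - self.center[1])
        return rho <= self.boundary_radius(rows, cols) - margin

    def normalized_boundary_dist(self, rows, cols) -> np.ndarray:
        """1 - rho / r(theta), clipped to [0, 1]."""
        rows = np.atleast_1d(np.asarray(rows, dtype=float))
        cols = np.atleast_1d(np.asarray(cols, dtype=float))
        rho = np.hypot(rows - self.center[0], cols - self.center[1])
        rb = self.boundary_radius(rows, cols)
        return np.clip(1.0 - rho / np.maximum(rb, 1e-9), 0.0, 1.0)


def _place_colonies(cfg: SimConfig, rng: np.random.Generator) -> list[_ColonyShape]:
    rows, cols = cfg.field_shape
    shapes: list[_ColonyShape] = []
    lo, hi = cfg.colony_radius_range
    max_extent = hi * 1.3  # radial blob can exceed R by up to 0.3
    if cfg.n_colonies > 0 and (rows < 2 * max_extent or cols < 2 * max_extent):
        raise PackingError(
            f"field {cfg.field_shape} too small to contain a colony of radius "
            f"up to {hi} (with boundary perturbation)"
        )
    # dart-throwing with whole-configuration restarts: a greedy sequence can
    # paint itself into a corner at packable densities
    for _restart in range(25):
        shapes = []
        ok_all = True
        for _ in range(cfg.n_colonies):
            R = rng.uniform(lo, hi)
            extent = R * 1.3
            placed = False
            for _attempt in range(2000):
                r0 = rng.uniform(extent, rows - extent)
                c0 = rng.uniform(extent, cols - extent)
                ok = all(
                    math.hypot(r0 - s.center[0], c0 - s.center[1])
                    > 1.15 * (R + s.R) + 4.0
                    for s in shapes
                )
                if ok:
                    shapes.append(_ColonyShape((r0, c0), R, rng))
                    placed = True
                    break
            if not placed:
                ok_all = False
                break
        if ok_all:
            return shapes
    raise PackingError(
        f"could not place {cfg.n_colonies} non-overlapping colonies of "
        f"radius {lo}-{hi} in a {rows}x{cols} field"
    )


def _pack_nuclei(
    shape: _ColonyShape, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-spacing rejection sampling of nucleus centres in a colony.

    Returns (centres (n, 2), radii (n,)).  With ``cells_per_colony`` None,
    packs until 400 consecutive rejections (saturation); otherwise raises
    :class:`PackingError` if the requested count cannot be placed.
    """
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    placed_r = np.empty((0,))
    placed_rc = np.empty((0, 2))
    target = cfg.cells_per_colony
    # saturation: stop after 400 consecutive rejections; with a requested
    # count, allow a longer stall before declaring the density infeasible
    max_consecutive = 400 if target is None else 2000
    max_attempts = (target or 10_000) * 500
    consecutive = 0
    attempts = 0
    while attempts < max_attempts:
        if target is not None and len(centres) >= target:
            break
        if consecutive >= max_consecutive:
            break
        attempts += 1
        rad = max(rng.normal(cfg.nucleus_radius_mean, cfg.nucleus_radius_sd), 1.5)
        rho = shape.R * 1.3 * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        r0 = shape.center[0] + rho * math.sin(theta)
        c0 = shape.center[1] + rho * math.cos(theta)
        if not shape.contains(r0, c0, margin=rad)[0]:
            consecutive += 1
            continue
        if len(centres):
            d = np.hypot(placed_rc[:, 0] - r0, placed_rc[:, 1] - c0)
            min_d = cfg.packing_min_spacing * (placed_r + rad)
            if (d < min_d).any():
                consecutive += 1
                continue
        centres.append((r0, c0))
        radii.append(rad)
        placed_rc = np.asarray(centres)
        placed_r = np.asarray(radii)
        consecutive = 0
    if target is not None and len(centres) < target:
        raise PackingError(
            f"placed only {len(centres)}/{target} nuclei in colony at "
            f"{shape.center}: minimum spacing "
            f"{cfg.packing_min_spacing} x (r_i + r_j) cannot accommodate the "
            "requested density"
        )
    return np.asarray(centres).reshape(-1, 2), np.asarray(radii)


def _place_delaminated(
    shapes: list[_ColonyShape], cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = cfg.field_shape
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(cfg.n_delaminated):
        for _attempt in range(500):
            rad = max(rng.normal(cfg.nucleus_radius_mean, cfg.nucleus_radius_sd), 1.5)
            r0 = rng.uniform(2 * rad, rows - 2 * rad)
            c0 = rng.uniform(2 * rad, cols - 2 * rad)
            if any(s.contains(r0, c0, margin=-3 * rad)[0] for s in shapes):
                continue
            if centres:
                arr = np.asarray(centres)
                d = np.hypot(arr[:, 0] - r0, arr[:, 1] - c0)
                if (d < cfg.packing_min_spacing * (np.asarray(radii) + rad)).any():
                    continue
            centres.append((r0, c0))
            radii.append(rad)
            break
        # silently place fewer if the field is crowded; delaminated count
        # is a nuisance parameter, not a contract
    return np.asarray(centres).reshape(-1, 2), np.asarray(radii)


# --------------------------------------------------------------------------
# Phenotype allocation
# --------------------------------------------------------------------------


def _allocate_phenotypes(
    n: int, edge_dist: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Assign quadrant phenotypes preserving marginal fractions.

    Class counts are multinomial draws from ``phenotype_fractions``.  The
    edge-biased class is then allocated to specific cells by weighted
    sampling without replacement with weight ``exp(-edge_bias * d)`` (d =
    normalized boundary distance; delaminated cells have d = 0 and so carry
    maximal weight); the remaining classes are assigned by a uniform random
    permutation of the remaining cells.
    """
    fracs = np.array([cfg.phenotype_fractions[p] for p in PHENOTYPES])
    counts = rng.multinomial(n, fracs / fracs.sum())
    phenotype = np.empty(n, dtype=object)
    edge_idx = PHENOTYPES.index(cfg.edge_phenotype)
    k = counts[edge_idx]
    all_idx = np.arange(n)
    if k > 0:
        w = np.exp(-cfg.edge_bias * edge_dist)
        chosen = rng.choice(all_idx, size=k, replace=False, p=w / w.sum())
    else:
        chosen = np.empty(0, dtype=int)
    phenotype[chosen] = cfg.edge_phenotype
    rest = np.setdiff1d(all_idx, chosen)
    rest = rng.permutation(rest)
    pos = 0
    for i, ph in enumerate(PHENOTYPES):
        if i == edge_idx:
            continue
        phenotype[rest[pos : pos + counts[i]]] = ph
        pos += counts[i]
    return phenotype


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _render_kernel(
    canvas: np.ndarray,
    r0: float,
    c0: float,
    radius: float,
    amplitude: float,
    sigma_frac: float,
    support_frac: float,
) -> None:
    """Add an isotropic Gaussian-profile disc with hard support."""
    support = support_frac * radius
    rows, cols = canvas.shape
    rlo = max(int(math.floor(r0 - support)), 0)
    rhi = min(int(math.ceil(r0 + support)) + 1, rows)
    clo = max(int(math.floor(c0 - support)), 0)
    chi = min(int(math.ceil(c0 + support)) + 1, cols)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.meshgrid(
        np.arange(rlo, rhi, dtype=float), np.arange(clo, chi, dtype=float), indexing="ij"
    )
    rho2 = (rr - r0) ** 2 + (cc - c0) ** 2
    sigma = sigma_frac * radius
    kern = np.exp(-rho2 / (2.0 * sigma**2))
    kern[rho2 > support**2] = 0.0
    canvas[rlo:rhi, clo:chi] += amplitude * kern


# Kernel geometry per channel: (sigma / radius, hard support / radius).
# The DNA stain is rendered wide (sigma = 2/3 r, support 2 r) so that
# adjacent nuclei genuinely merge in the nuclear channel and exercise the
# splitting step.  Marker chromophores are confined to the cell proper —
# the transcription factor strictly to the nucleus, the surface marker to
# the nucleus plus a small membrane annulus (cells are tightly packed with
# scant cytoplasm) — keeping neighbour crosstalk in the measured nucleus
# areas small.  Measurement downstream is always over the nucleus area.
_KERNELS = {
    "nuclear": (2.0 / 3.0, 2.0),
    "marker_x": (0.5, 1.0),
    "marker_y": (0.4, 1.1),
}


def _build_truth(cfg: SimConfig, rng: np.random.Generator) -> tuple[GroundTruth, list[_ColonyShape]]:
    shapes = _place_colonies(cfg, rng)

    centres_list, radii_list, colony_ids, edge_d = [], [], [], []
    for cid, shape in enumerate(shapes, start=1):
        rc, rad = _pack_nuclei(shape, cfg, rng)
        if len(rc):
            centres_list.append(rc)
            radii_list.append(rad)
            colony_ids.append(np.full(len(rc), cid))
            edge_d.append(shape.normalized_boundary_dist(rc[:, 0], rc[:, 1]))
    rc_out, rad_out = _place_delaminated(shapes, cfg, rng)
    if len(rc_out):
        centres_list.append(rc_out)
        radii_list.append(rad_out)
        colony_ids.append(np.zeros(len(rc_out), dtype=int))
        edge_d.append(np.zeros(len(rc_out)))

    if centres_list:
        centres = np.concatenate(centres_list)
        radii = np.concatenate(radii_list)
        colony_id = np.concatenate(colony_ids).astype(int)
        edge_dist = np.concatenate(edge_d)
    else:
        centres = np.empty((0, 2))
        radii = np.empty(0)
        colony_id = np.empty(0, dtype=int)
        edge_dist = np.empty(0)
    n = len(centres)

    if n:
        phenotype = _allocate_phenotypes(n, edge_dist, cfg, rng)
    else:
        phenotype = np.empty(0, dtype=object)

    expr = {}
    for ch in CHANNELS:
        vals = np.empty(n)
        for ph in PHENOTYPES:
            m = phenotype == ph
            if m.any():
                mu, sigma = cfg.expression_params[ph][ch]
                vals[m] = rng.lognormal(mu, sigma, size=int(m.sum()))
        expr[ch] = vals

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "row": centres[:, 0] if n else np.empty(0),
            "col": centres[:, 1] if n else np.empty(0),
            "radius": radii,
            "colony_id": colony_id,
            "boundary_dist_norm": edge_dist,
            "phenotype": phenotype,
            "expr_nuclear": expr["nuclear"] if n else np.empty(0),
            "expr_marker_x": expr["marker_x"] if n else np.empty(0),
            "expr_marker_y": expr["marker_y"] if n else np.empty(0),
        }
    )
    colonies = pd.DataFrame(
        {
            "colony_id": np.arange(1, len(shapes) + 1),
            "row": [s.center[0] for s in shapes],
            "col": [s.center[1] for s in shapes],
            "radius": [s.R for s in shapes],
        }
    )
    return GroundTruth(cells=cells, colonies=colonies), shapes


def generate_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Ground truth only, skipping camera rendering.

    Identical to the ground truth returned by :func:`generate_colony_field`
    for the same config (background noise is drawn after all latent draws,
    so skipping it does not perturb the stream).  Useful when only the
    dissociated/latent specimen is needed, e.g. for the flow arm.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth, _ = _build_truth(cfg, rng)
    return truth


def generate_colony_field(cfg: SimConfig) -> tuple[ImageField, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Draw order (single generator, seeded from ``cfg.seed``): colony
    geometry → per-colony nucleus packing → delaminated cells → phenotype
    counts and edge-weighted allocation → per-channel true expression →
    per-channel background noise.  Identical config (including seed) gives
    bit-identical images and tables.

    Raises
    ------
    PackingError
        If colonies or the requested nucleus density cannot be placed under
        the minimum-spacing constraint.
    ValueError
        For an invalid config (zero-area field, bad fractions, ...).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth, _shapes = _build_truth(cfg, rng)

    cells = truth.cells
    n = len(cells)
    centres = cells[["row", "col"]].to_numpy(float).reshape(n, 2)
    radii = cells["radius"].to_numpy(float)
    expr = {ch: cells[f"expr_{ch}"].to_numpy(float) for ch in CHANNELS}

    channels = {}
    for ch in CHANNELS:
        canvas = np.zeros(cfg.field_shape, dtype=float)
        sigma_frac, support_frac = _KERNELS[ch]
        amp = expr[ch] if ch == "nuclear" else cfg.camera_gain * expr[ch]
        for i in range(n):
            _render_kernel(
                canvas, centres[i, 0], centres[i, 1], radii[i], amp[i],
                sigma_frac, support_frac,
            )
        canvas += rng.normal(cfg.background_level, cfg.background_noise_sd, cfg.field_shape)
        channels[ch] = np.clip(np.rint(canvas), 0, cfg.camera_ceiling).astype(np.uint16)

    image = ImageField(
        channels=channels,
        channel_names={
            "nuclear": "Hoechst",
            "marker_x": cfg.marker_x_name,
            "marker_y": cfg.marker_y_name,
        },
    )
    return image, truth


# --------------------------------------------------------------------------
# Flow simulator
# --------------------------------------------------------------------------


def simulate_flow_readings(
    truth: GroundTruth, cfg: SimConfig, seed: Optional[int] = None
) -> FlowSample:
    """Dissociate the specimen and read it on a simulated flow cytometer.

    Per cell and channel: ``measured = true_expression * noise`` with
    mean-1 multiplicative lognormal noise of coefficient of variation
    ``cfg.flow_cv``, clipped to [0, 10**flow_decades].  The output row order
    is a random permutation (dissociation destroys spatial information).
    The generator is seeded from ``seed`` (default: derived from
    ``cfg.seed``), independently of the imaging draw stream.
    """
    if truth.n_cells == 0:
        raise ValueError("cannot simulate flow readings from an empty specimen")
    exprs = truth.cells[["expr_marker_x", "expr_marker_y"]].to_numpy(float)
    if (exprs < 0).any():
        raise ValueError("negative true expression: generator contract violation")
    if seed is None:
        seed = (cfg.seed * 2654435761 + 7) % 2**31
    rng = np.random.default_rng(seed)
    n = truth.n_cells
    if cfg.flow_cv > 0:
        sigma2 = math.log(1.0 + cfg.flow_cv**2)
        noise = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=exprs.shape)
    else:
        noise = np.ones_like(exprs)
    measured = np.clip(exprs * noise, 0.0, cfg.flow_ceiling)
    order = rng.permutation(n)
    readings = pd.DataFrame(
        {
            "cell_id": truth.cells["cell_id"].to_numpy()[order],
            "marker_x": measured[order, 0],
            "marker_y": measured[order, 1],
        }
    )
    return FlowSample(readings=readings, flow_ceiling=cfg.flow_ceiling)
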