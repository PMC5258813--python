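"""Nuclear segmentation of tightly packed colonies.

The DNA channel of a pluripotent-colony field is a carpet of touching
nuclei.  The segmentation operator is the classical recipe for that
regime: smooth, subtract a robust background estimate, global Otsu
threshold, fill holes, then split touching objects with a seeded watershed,
and finally filter by area and border policy.  Labels are relabelled to the
dense range 1..K.

Seeding note: inside a confluent colony the thresholded foreground is one
solid blob, so the distance transform of the mask carries no per-nucleus
saddles — its maxima track the colony outline, not the nuclei.  Seeds are
therefore taken from local maxima of the *smoothed intensity* (each nucleus
contributes one intensity peak even when fully merged in the mask), with a
per-object intensity floor of ``split_h`` x the object's maximum and a
minimum peak separation derived from ``min_nucleus_area``.  The watershed
then flows on inverted smoothed intensity within the mask.

The operator is fully deterministic for a fixed input and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import relabel_sequential, watershed


@dataclass
class SegmentationParams:
    """Tunable parameters of the nuclear segmentation operator.

    smoothing_sigma : pixels
        Gaussian pre-smoothing scale; of order half the nucleus radius.
    background_percentile : percent
        Per-image intensity percentile subtracted as the background
        estimate (robust to the fraction of the field covered by colonies).
    min_nucleus_area, max_nucleus_area : pixels^2
        Retained-object area band; fragments below and unresolved clumps
        above are discarded.
    split_h : dimensionless in [0, 1]
        Seed-suppression fraction: within each thresholded object only
        intensity peaks of at least ``split_h`` x the object's maximum
        (above background) seed the watershed.  1 disables splitting
        entirely (plain connected components); small values split
        aggressively.
    shrink_radius : pixels (integer >= 0)
        After splitting, each region is eroded by this many pixels (largest
        4-connected piece kept), so the reported "processed nucleus area" is
        the nucleus *interior*.  In a confluent colony the watershed tiles
        the whole foreground blob, so unshrunk regions would reach the
        inter-nuclear boundary where the abutting neighbours' membrane
        signal lives; 0 disables shrinking.
    border_policy : "keep" | "discard"
        Whether objects touching the field border are retained.
    """

    smoothing_sigma: float = 2.0
    background_percentile: float = 5.0
    min_nucleus_area: int = 25
    max_nucleus_area: int = 400
    split_h: float = 0.3
    shrink_radius: int = 2
    border_policy: str = "keep"

    def validate(self) -> None:
        if not 0 < self.min_nucleus_area < self.max_nucleus_area:
            raise ValueError(
                "need 0 < min_nucleus_area < max_nucleus_area, got "
                f"{self.min_nucleus_area}, {self.max_nucleus_area}"
            )
        if not 0.0 <= self.split_h <= 1.0:
            raise ValueError(f"split_h must be in [0, 1], got {self.split_h}")
        if self.shrink_radius < 0:
            raise ValueError(f"shrink_radius must be >= 0, got {self.shrink_radius}")
        if self.border_policy not in ("keep", "discard"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if not 0.0 <= self.background_percentile <= 100.0:
            raise ValueError("background_percentile must be a percent in [0, 100]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SegmentationParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _smooth_subtract(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    smoothed = gaussian(image.astype(float), sigma=params.smoothing_sigma,
                        preserve_range=True)
    bg = np.percentile(smoothed, params.background_percentile)
    return np.clip(smoothed - bg, 0.0, None)


def _threshold_mask(sub: np.ndarray) -> np.ndarray:
    if sub.max() <= sub.min():  # constant (e.g. background-only) image
        return np.zeros(sub.shape, dtype=bool)
    thr = threshold_otsu(sub)
    # Otsu splits even pure camera noise; demand that the threshold clears
    # the robust background spread before declaring any foreground
    noise = 1.4826 * np.median(np.abs(sub - np.median(sub)))
    if thr <= 8.0 * noise:
        return np.zeros(sub.shape, dtype=bool)
    mask = sub > thr
    return ndi.binary_fill_holes(mask, structure=_STRUCT4)


def _split_markers(mask: np.ndarray, sub: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Watershed seeds: per-object intensity peaks at least
    ``split_h`` x the object's intensity maximum, separated by at least the
    radius implied by ``min_nucleus_area``.  Objects yielding fewer than two
    peaks keep a single seed at their intensity maximum."""
    min_sep = max(int(round(0.8 * np.sqrt(params.min_nucleus_area / np.pi))), 2)
    objects, _ = ndi.label(mask, structure=_STRUCT4)
    markers = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    for idx, sl in enumerate(ndi.find_objects(objects), start=1):
        obj = objects[sl] == idx
        s = np.where(obj, sub[sl], 0.0)
        smax = s.max()
        if smax <= 0:
            continue
        peaks = peak_local_max(
            s,
            min_distance=min_sep,
            threshold_abs=params.split_h * smax,
            exclude_border=False,
        )
        if len(peaks) < 2:
            peaks = np.array([np.unravel_index(np.argmax(s), s.shape)])
        sub_markers = markers[sl]
        for k, (pr, pc) in enumerate(peaks):
            sub_markers[pr, pc] = next_label + k
        next_label += len(peaks)
    return markers


def _shrink_regions(labels: np.ndarray, radius: int) -> np.ndarray:
    """Erode every region by ``radius`` pixels (4-connected erosion),
    keeping the largest remaining 4-connected piece."""
    out = np.zeros_like(labels)
    pad = radius + 1
    for idx, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        sl_pad = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, labels.shape)
        )
        region = labels[sl_pad] == idx
        core = ndi.binary_erosion(region, structure=_STRUCT4, iterations=radius)
        if not core.any():
            continue
        pieces, k = ndi.label(core, structure=_STRUCT4)
        if k > 1:
            sizes = ndi.sum_labels(core, pieces, index=np.arange(1, k + 1))
            core = pieces == (1 + int(np.argmax(sizes)))
        out[sl_pad][core] = idx
    return out


def segment_nuclei(image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei in a 2-D DNA-stain image.

    Returns an ``int32`` label mask with dense labels 1..K and 0 as
    background.  A constant or empty image yields zero labels; non-2-D
    input is an error.
    """
    if params is None:
        params = SegmentationParams()
    params.validate()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    if image.size == 0:
        raise ValueError("zero-area image")

    sub = _smooth_subtract(image, params)
    mask = _threshold_mask(sub)
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)

    if params.split_h >= 1.0:
        # no-split mode: plain 4-connected components of the mask
        labels, _ = ndi.label(mask, structure=_STRUCT4)
    else:
        markers = _split_markers(mask, sub, params)
        labels = watershed(-sub, markers=markers, mask=mask, connectivity=1)
        if params.shrink_radius > 0:
            labels = _shrink_regions(labels, params.shrink_radius)

    # area band
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    bad = ids[(counts < params.min_nucleus_area) | (counts > params.max_nucleus_area)]
    if bad.size:
        labels[np.isin(labels, bad)] = 0

    if params.border_policy == "discard":
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        border = border[border > 0]
        if border.size:
            labels[np.isin(labels, border)] = 0

    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def stitch_tiles(tiles: list[np.ndarray], grid: tuple[int, int]) -> np.ndarray:
    """Abutting row-major mosaic of equally shaped tiles (no overlap, no
    blending).  Pixel (r, c) of tile (i, j) lands at (i*h + r, j*w + c)."""
    rows, cols = grid
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid must be positive, got {grid}")
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles for grid {grid}, got {len(tiles)}")
    tiles = [np.asarray(t) for t in tiles]
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("all tiles must share one shape")
    if len(shape) != 2:
        raise ValueError("tiles must be 2-D")
    h, w = shape
    out = np.empty((rows * h, cols * w), dtype=tiles[0].dtype)
    for i in range(rows):
        for j in range(cols):
            out[i * h : (i + 1) * h, j * w : (j + 1) * w] = tiles[i * cols + j]
    return out
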