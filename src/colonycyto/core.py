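"""Shared containers for multi-channel fields and label masks.

An :class:`ImageField` holds one 2-D image per channel *role*.  Roles are
fixed — ``nuclear`` (DNA stain), ``marker_x`` (transcription-factor marker,
e.g. OCT-3/4) and ``marker_y`` (surface marker, e.g. SSEA1) — while the
display names of the two markers travel in :attr:`ImageField.channel_names`.
Label masks are plain ``int32`` arrays with 0 = background and dense labels
1..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Channel roles, in the page order used for TIFF round trips.
CHANNELS: tuple[str, ...] = ("nuclear", "marker_x", "marker_y")


@dataclass
class ImageField:
    """A multi-channel 2-D fluorescence field.

    Parameters
    ----------
    channels
        Mapping of channel role to a 2-D array.  All channels share one
        shape.  Camera output is ``uint16`` (12-bit counts stored in 16-bit
        pages) but float arrays are accepted for intermediate products.
    pixel_size_um
        Physical pixel pitch, micrometres.  Informational only; every
        distance in the package is expressed in pixels.
    channel_names
        Optional role → display-name mapping (e.g. ``marker_y`` → ``SSEA1``).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    channel_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D (ndim={arr.ndim})")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; have {sorted(self.channels)}"
            ) from None

    # ---- TIFF round trip -------------------------------------------------
    def to_tiff(self, path) -> None:
        """Write as a multi-page 16-bit TIFF, one page per role in
        :data:`CHANNELS` order (missing roles are skipped)."""
        roles = [r for r in CHANNELS if r in self.channels]
        stack = np.stack(
            [np.asarray(self.channels[r], dtype=np.uint16) for r in roles]
        )
        tifffile.imwrite(path, stack, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, roles: tuple[str, ...] = CHANNELS) -> "ImageField":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.shape[0] > len(roles):
            raise ValueError(
                f"{data.shape[0]} pages but only {len(roles)} channel roles"
            )
        return cls(channels={r: data[i] for i, r in enumerate(roles[: data.shape[0]])})


def write_labels(path, labels: np.ndarray) -> None:
    """Persist a label mask as 16-bit TIFF (errors above 65535 labels)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
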