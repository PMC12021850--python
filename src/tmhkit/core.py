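"""Core raster containers and shared constants.

Coordinate convention used everywhere in this package: images are 2-D arrays
indexed ``[row, col]`` with the row index increasing *downward*, matching the
raster display of ocular photographs.  "Lowest point" therefore always means
the pixel with the *maximum* row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Clinical dry-eye screening criterion: tear meniscus height strictly below
#: this value (in mm) is labelled dry eye.
DRY_EYE_THRESHOLD_MM = 0.20


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


class NoMeniscusError(RuntimeError):
    """A mask contains no foreground pixels: nothing to measure.

    Deliberately distinct from I/O errors so that batch drivers can tell a
    readable-but-empty segmentation from an unreadable file.
    """


class UndefinedMetricError(ValueError):
    """A classification metric has a zero denominator (an empty class)."""


class ManifestError(ValueError):
    """A dataset manifest violates its schema."""


def as_bool_mask(mask) -> np.ndarray:
    """Coerce a :class:`MeniscusMask` or array-like to a 2-D boolean array."""
    if isinstance(mask, MeniscusMask):
        return mask.pixels
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    return arr.astype(bool)


@dataclass
class OcularImage:
    """A grayscale ocular-surface image with pixel calibration.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with intensities in ``[0, 1]``.
    mm_per_px : float
        Physical size of one pixel in millimetres (isotropic).
    source_id : str
        Identifier tying the image to its manifest record.
    """

    pixels: np.ndarray
    mm_per_px: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 32 or w < 32:
            raise ValueError(f"image must be at least 32x32 pixels, got {h}x{w}")
        if self.mm_per_px <= 0:
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_uint8(cls, raw: np.ndarray, mm_per_px: float, source_id: str = "") -> "OcularImage":
        """Build from an 8-bit raster, normalising intensities to [0, 1]."""
        return cls(np.asarray(raw, dtype=float) / 255.0, mm_per_px, source_id)


@dataclass
class MeniscusMask:
    """A binary raster marking the tear meniscus area.

    Shares its pixel grid with the image it was derived from; may be empty.
    """

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = as_bool_mask(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeniscusMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.pixels, other.pixels))
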