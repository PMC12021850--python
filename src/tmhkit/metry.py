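"""Tear-meniscus-height measurement from a binary mask.

The measurement follows the gravity argument for the tear meniscus: the tear
pool's tangent at its lowest point is (near-)horizontal, so the height is
read as a vertical chord there.  Concretely: keep the largest 8-connected
component, find the lowest foreground pixel (maximum row; ties broken by the
lower-median column), and count the contiguous vertical run of foreground
pixels through that point.  Multiplying by the calibration gives TMH in mm,
and a strict ``tmh_mm < threshold`` comparison yields the dry-eye label.

All measurements are integer-pixel: no sub-pixel interpolation is attempted,
matching the mask-based definition of the quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DRY_EYE_THRESHOLD_MM, MeniscusMask, NoMeniscusError, as_bool_mask

__all__ = [
    "TMHMeasurement",
    "largest_component",
    "lowest_point",
    "vertical_chord",
    "measure_tmh",
    "measure_batch",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TMHMeasurement:
    """One TMH reading: where it was taken, its extent, and the screening call."""

    lowest_point: tuple[int, int]
    tmh_px: int
    tmh_mm: float
    dry_eye: bool
    component_area_px: int
    n_components_discarded: int


def largest_component(mask) -> MeniscusMask:
    """Retain only the largest 8-connected component of ``mask``.

    Empty masks pass through unchanged.  When two components tie on area, the
    one whose lowest pixel has the larger row index (i.e. the lower one on
    screen) is kept — the tear meniscus is the bottom structure in the image.
    """
    pixels = as_bool_mask(mask)
    labels, n = ndimage.label(pixels, structure=_EIGHT_CONNECTED)
    if n <= 1:
        return MeniscusMask(pixels.copy())
    areas = np.bincount(labels.ravel())[1:]  # skip background
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if candidates.size == 1:
        keep = candidates[0]
    else:
        rows = np.nonzero(pixels)[0]
        labelled_rows = labels[pixels.astype(bool)]
        bottoms = [rows[labelled_rows == lab].max() for lab in candidates]
        keep = candidates[int(np.argmax(bottoms))]
    return MeniscusMask(labels == keep)


def count_components(mask) -> int:
    """Number of 8-connected foreground components."""
    return int(ndimage.label(as_bool_mask(mask), structure=_EIGHT_CONNECTED)[1])


def lowest_point(mask) -> tuple[int, int]:
    """Lowest foreground pixel: maximum row, lower-median column at that row."""
    pixels = as_bool_mask(mask)
    rows, cols = np.nonzero(pixels)
    if rows.size == 0:
        raise NoMeniscusError("mask contains no foreground pixels")
    r = int(rows.max())
    at_bottom = np.sort(cols[rows == r])
    return r, int(at_bottom[(at_bottom.size - 1) // 2])


def vertical_chord(mask, point: tuple[int, int]) -> int:
    """Length of the contiguous vertical foreground run through ``point``.

    Counts inclusively within the column of ``point``; disjoint runs higher
    in the same column (e.g. reflection artifacts) are excluded.
    """
    pixels = as_bool_mask(mask)
    r, c = point
    if not (0 <= r < pixels.shape[0] and 0 <= c < pixels.shape[1]) or not pixels[r, c]:
        raise ValueError(f"point {point} is not a foreground pixel of the mask")
    column = pixels[:, c]
    top = r
    while top > 0 and column[top - 1]:
        top -= 1
    bottom = r
    while bottom < column.size - 1 and column[bottom + 1]:
        bottom += 1
    return bottom - top + 1


def measure_tmh(
    mask,
    mm_per_px: float,
    threshold_mm: float = DRY_EYE_THRESHOLD_MM,
) -> TMHMeasurement:
    """Measure TMH on a mask: largest component -> lowest point -> chord.

    Raises :class:`NoMeniscusError` for an empty mask.  The dry-eye label is
    ``tmh_mm < threshold_mm`` with a strict inequality: a meniscus of exactly
    the criterion height is not dry.
    """
    if mm_per_px <= 0:
        raise ValueError(f"mm_per_px must be positive, got {mm_per_px}")
    pixels = as_bool_mask(mask)
    n_total = count_components(pixels)
    component = largest_component(pixels)
    if component.is_empty:
        raise NoMeniscusError("mask contains no foreground pixels")
    point = lowest_point(component)
    tmh_px = vertical_chord(component, point)
    tmh_mm = tmh_px * mm_per_px
    return TMHMeasurement(
        lowest_point=point,
        tmh_px=tmh_px,
        tmh_mm=tmh_mm,
        dry_eye=tmh_mm < threshold_mm,
        component_area_px=component.area,
        n_components_discarded=n_total - 1,
    )


BATCH_COLUMNS = ["source_id", "row", "col", "tmh_px", "tmh_mm", "dry_eye", "flag"]


def measure_batch(
    manifest,
    mask_source,
    mm_per_px: float | None = None,
    threshold_mm: float = DRY_EYE_THRESHOLD_MM,
) -> pd.DataFrame:
    """Measure every record of a manifest, one row per image, order preserved.

    ``mask_source`` is either a segmenter (any object with a
    ``predict(image) -> MeniscusMask`` method, applied to the record's image)
    or a callable ``record -> MeniscusMask`` (e.g. a ground-truth mask
    reader).  Failures — unreadable files, empty masks — do not abort the
    batch: the row is flagged with the failure reason and its numeric fields
    are left missing.
    """
    from . import io as tio

    mm = mm_per_px if mm_per_px is not None else manifest.mm_per_px
    if hasattr(mask_source, "predict"):
        def get_mask(record):
            image = tio.read_image(manifest.resolve(record.image_path), mm)
            return mask_source.predict(image)
    elif callable(mask_source):
        get_mask = mask_source
    else:
        raise TypeError("mask_source must be a segmenter or a callable record -> mask")

    rows = []
    for record in manifest.records:
        try:
            m = measure_tmh(get_mask(record), mm, threshold_mm)
            rows.append(
                {
                    "source_id": record.source_id,
                    "row": m.lowest_point[0],
                    "col": m.lowest_point[1],
                    "tmh_px": m.tmh_px,
                    "tmh_mm": m.tmh_mm,
                    "dry_eye": m.dry_eye,
                    "flag": "",
                }
            )
        except NoMeniscusError:
            rows.append(_failed_row(record.source_id, "no-meniscus"))
        except (OSError, ValueError) as exc:
            rows.append(_failed_row(record.source_id, f"read-error: {exc}"))
    return pd.DataFrame(rows, columns=BATCH_COLUMNS)


def _failed_row(source_id: str, flag: str) -> dict:
    return {
        "source_id": source_id,
        "row": pd.NA,
        "col": pd.NA,
        "tmh_px": pd.NA,
        "tmh_mm": np.nan,
        "dry_eye": pd.NA,
        "flag": flag,
    }
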