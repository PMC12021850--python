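"""Independent brute-force oracles and random-input generators for the tests.

Everything here is deliberately written the slow, obvious way (python loops,
flood fill, pairwise enumeration) so it shares no code path with the package
implementations it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter


# ---------------------------------------------------------------------------
# brute-force TMH measurement (full pixel scan)
# ---------------------------------------------------------------------------

def brute_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by flood fill, in raster order of first pixel."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    components = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                components.append(comp)
    return components


def brute_lowest_point(pixels: set[tuple[int, int]]) -> tuple[int, int]:
    rmax = max(r for r, _ in pixels)
    cols = sorted(c for r, c in pixels if r == rmax)
    return rmax, cols[(len(cols) - 1) // 2]


def brute_chord(pixels: set[tuple[int, int]], point: tuple[int, int]) -> int:
    r, c = point
    length = 1
    rr = r - 1
    while (rr, c) in pixels:
        length += 1
        rr -= 1
    rr = r + 1
    while (rr, c) in pixels:
        length += 1
        rr += 1
    return length


def brute_measure(mask: np.ndarray, mm_per_px: float, threshold_mm: float = 0.20):
    """Full-scan reference for measure_tmh; returns the same tuple of facts."""
    components = brute_components(mask)
    if not components:
        return None
    best = components[0]
    for comp in components[1:]:
        if len(comp) > len(best):
            best = comp
        elif len(comp) == len(best):
            if max(r for r, _ in comp) > max(r for r, _ in best):
                best = comp
    point = brute_lowest_point(best)
    px = brute_chord(best, point)
    mm = px * mm_per_px
    return {
        "lowest_point": point,
        "tmh_px": px,
        "tmh_mm": mm,
        "dry_eye": mm < threshold_mm,
        "component_area_px": len(best),
        "n_components_discarded": len(components) - 1,
    }


# ---------------------------------------------------------------------------
# random masks
# ---------------------------------------------------------------------------

def random_mask(rng: np.random.Generator, shape=(40, 56), allow_empty=False) -> np.ndarray:
    """A varied random binary mask: smoothed-noise blobs, boxes, or sparse dots."""
    h, w = shape
    kind = rng.integers(3)
    if kind == 0:
        field = gaussian_filter(rng.normal(size=shape), sigma=rng.uniform(1.5, 4.0))
        mask = field > np.quantile(field, rng.uniform(0.7, 0.95))
    elif kind == 1:
        mask = np.zeros(shape, dtype=bool)
        for _ in range(rng.integers(1, 4)):
            r, c = rng.integers(0, h - 4), rng.integers(0, w - 4)
            mask[r:r + rng.integers(2, h // 2), c:c + rng.integers(2, w // 2)] = True
    else:
        mask = rng.random(shape) < rng.uniform(0.01, 0.08)
    if not allow_empty and not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    return mask


# ---------------------------------------------------------------------------
# rank-statistic AUC (pairwise enumeration, ties = 1/2)
# ---------------------------------------------------------------------------

def brute_auc_from_scores(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    concordant = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                concordant += 1.0
            elif p == q:
                concordant += 0.5
    return concordant / (len(pos) * len(neg))
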