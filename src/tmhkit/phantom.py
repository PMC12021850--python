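"""Synthetic ocular-surface phantoms with exact ground-truth meniscus masks.

A phantom emulates the salient geometry of an infrared Keratograph-style
ocular-surface photograph: a mid-grey background, a darker corneal ellipse,
and a thin bright tear-meniscus band pooled along the lower-eyelid margin.
The eyelid margin is a parabola in pixel coordinates whose apex is the
on-screen lowest point (maximum row index); the meniscus band is the region
between the margin and its vertical upward offset by a (possibly sinusoidally
modulated) local thickness.  The whole geometry can be rotated to emulate a
tilted eyelid, and an illumination ramp plus additive Gaussian noise corrupt
the image — never the mask.

Ground truth is defined on the *noiseless rasterized mask*: the true TMH is
the vertical chord of that raster at its lowest point, measured by a direct
pixel scan internal to this module.  This keeps the ground truth exact at the
pixel level while agreeing with the continuous band geometry to within one
pixel (asserted against a supersampled oracle in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import (
    DRY_EYE_THRESHOLD_MM,
    MeniscusMask,
    OcularImage,
    PhantomSpecError,
)

__all__ = [
    "PhantomSpec",
    "AnnotatedSample",
    "generate_phantom",
    "generate_cohort",
    "default_spec_sampler",
    "write_dataset",
]

# Default rendering intensities (before ramp/noise, clipped to [0, 1]).
BACKGROUND_INTENSITY = 0.15
CORNEA_INTENSITY = 0.05
BAND_INTENSITY = 0.85


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters fully determining one phantom and its analytic ground truth.

    Attributes
    ----------
    eyelid_coeffs : (a, b, c)
        Eyelid-margin parabola ``margin_row(col) = c - a * (col - b)**2`` with
        ``a > 0``: the apex ``(c, b)`` is the margin's maximum-row point, i.e.
        the on-screen lowest point of the band, and the arms curve upward.
    meniscus_thickness_mm : float
        Nominal vertical band thickness at the apex, in mm.
    thickness_modulation : float
        Relative sinusoidal thickness variation along the eyelid, in [0, 1);
        phase is zero at the apex so the nominal thickness is preserved there.
    tilt_deg : float
        Global rotation of the eyelid geometry about the image centre
        (positive = counter-clockwise in screen (col, row) coordinates).
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise.
    illum_gradient : float
        Amplitude of a horizontal linear brightness ramp (edge-to-centre
        difference of ``illum_gradient / 2``).
    """

    width_px: int = 128
    height_px: int = 128
    mm_per_px: float = 0.01
    eyelid_coeffs: tuple[float, float, float] = (0.004, 64.0, 96.0)
    meniscus_thickness_mm: float = 0.20
    thickness_modulation: float = 0.0
    tilt_deg: float = 0.0
    noise_sd: float = 0.0
    illum_gradient: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`PhantomSpecError` naming the first violated invariant."""
        a, b, c = self.eyelid_coeffs
        if self.width_px < 32 or self.height_px < 32:
            raise PhantomSpecError(
                f"image must be at least 32x32 px, got {self.height_px}x{self.width_px}"
            )
        if self.mm_per_px <= 0:
            raise PhantomSpecError(f"mm_per_px must be positive, got {self.mm_per_px}")
        if a <= 0:
            raise PhantomSpecError(f"parabola coefficient a must be positive, got {a}")
        if self.meniscus_thickness_mm <= 0:
            raise PhantomSpecError(
                f"meniscus_thickness_mm must be positive, got {self.meniscus_thickness_mm}"
            )
        if self.thickness_px < 2:
            raise PhantomSpecError(
                "band must span at least 2 pixels vertically: "
                f"thickness {self.meniscus_thickness_mm} mm / {self.mm_per_px} mm/px "
                f"= {self.thickness_px:.2f} px"
            )
        if not (0 <= self.thickness_modulation < 1):
            raise PhantomSpecError(
                f"thickness_modulation must lie in [0, 1), got {self.thickness_modulation}"
            )
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if not (0 <= b < self.width_px and 0 <= c < self.height_px):
            raise PhantomSpecError(
                f"eyelid apex (row={c}, col={b}) lies outside the "
                f"{self.height_px}x{self.width_px} image"
            )
        t_max = self.thickness_px * (1 + self.thickness_modulation)
        if c - t_max < 0:
            raise PhantomSpecError(
                f"band exceeds the top of the image: apex row {c} minus maximum "
                f"thickness {t_max:.1f} px is negative"
            )

    @property
    def thickness_px(self) -> float:
        """Nominal band thickness in pixels (real-valued)."""
        return self.meniscus_thickness_mm / self.mm_per_px


@dataclass
class AnnotatedSample:
    """A phantom image, its exact mask, and the analytic ground truth.

    ``true_tmh_mm`` is the vertical chord of the noiseless rasterized band at
    its lowest point; ``dry_eye_label`` is ``true_tmh_mm < 0.20 mm`` (strict).
    """

    image: OcularImage
    mask: MeniscusMask
    true_tmh_mm: float
    dry_eye_label: bool
    spec: PhantomSpec


def _untilted_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (row, col) coordinates mapped back into the untilted frame."""
    rows, cols = np.meshgrid(
        np.arange(spec.height_px, dtype=float),
        np.arange(spec.width_px, dtype=float),
        indexing="ij",
    )
    if spec.tilt_deg == 0:
        return rows, cols
    theta = math.radians(spec.tilt_deg)
    cy = (spec.height_px - 1) / 2.0
    cx = (spec.width_px - 1) / 2.0
    dr, dc = rows - cy, cols - cx
    # inverse rotation: the geometry is rotated by +theta, so pixel
    # coordinates are pulled back by -theta before the analytic test
    r0 = cy + math.cos(theta) * dr - math.sin(theta) * dc
    c0 = cx + math.sin(theta) * dr + math.cos(theta) * dc
    return r0, c0


def _band_mask(spec: PhantomSpec) -> np.ndarray:
    """Analytic point-in-band test on the pixel grid (exact, no resampling)."""
    r0, c0 = _untilted_coords(spec)
    a, b, c = spec.eyelid_coeffs
    margin = c - a * (c0 - b) ** 2
    t_px = spec.thickness_px * (
        1.0 + spec.thickness_modulation * np.sin(2 * np.pi * (c0 - b) / spec.width_px)
    )
    return (r0 <= margin) & (r0 > margin - t_px)


def _cornea_mask(spec: PhantomSpec) -> np.ndarray:
    r0, c0 = _untilted_coords(spec)
    a, b, c = spec.eyelid_coeffs
    t_max = spec.thickness_px * (1 + spec.thickness_modulation)
    ry = 0.18 * spec.height_px
    rx = 0.30 * spec.width_px
    er = c - t_max - 6.0 - ry  # resting just above the band
    return ((r0 - er) / ry) ** 2 + ((c0 - b) / rx) ** 2 <= 1.0


def _scan_lowest_chord(mask: np.ndarray) -> int:
    """Direct pixel scan: vertical run length at the mask's lowest point.

    Lowest point = maximum row containing a foreground pixel; at that row the
    lower-median column is taken, and the contiguous vertical run through the
    point is counted.  Kept local to this module so the generator's ground
    truth does not depend on the measurement code it is used to validate.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise PhantomSpecError("generated band raster is empty")
    r = int(rows.max())
    at_bottom = np.sort(cols[rows == r])
    col = int(at_bottom[(at_bottom.size - 1) // 2])
    column = mask[:, col]
    top = r
    while top > 0 and column[top - 1]:
        top -= 1
    return r - top + 1


def generate_phantom(spec: PhantomSpec) -> AnnotatedSample:
    """Render one phantom.

    Deterministic given ``spec`` (including its seed); the mask is the exact
    noiseless band raster and only the image carries noise.
    """
    spec.validate()
    band = _band_mask(spec)
    chord_px = _scan_lowest_chord(band)
    true_tmh_mm = chord_px * spec.mm_per_px

    pixels = np.full((spec.height_px, spec.width_px), BACKGROUND_INTENSITY)
    pixels[_cornea_mask(spec)] = CORNEA_INTENSITY
    pixels[band] = BAND_INTENSITY
    if spec.illum_gradient != 0:
        ramp = spec.illum_gradient * (
            np.arange(spec.width_px) / (spec.width_px - 1) - 0.5
        )
        pixels = pixels + ramp[np.newaxis, :]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    image = OcularImage(pixels, spec.mm_per_px, source_id=f"phantom-{spec.seed}")
    return AnnotatedSample(
        image=image,
        mask=MeniscusMask(band),
        true_tmh_mm=true_tmh_mm,
        dry_eye_label=true_tmh_mm < DRY_EYE_THRESHOLD_MM,
        spec=spec,
    )


def default_spec_sampler(rng: np.random.Generator, thickness_mm: float) -> PhantomSpec:
    """Draw a realistic phantom geometry around a given band thickness.

    Apex position, eyelid curvature, tilt (up to +-10 degrees), thickness
    modulation (up to 30 %), illumination ramp and mild sensor noise are all
    varied; image size and calibration stay at the package defaults
    (128 x 128 px at 0.01 mm/px).

    Tilt slides the band's lowest point away from the apex, so the measured
    chord samples the *modulated* local thickness (inflated by 1/cos(tilt)).
    The modulation amplitude is therefore bounded so that every possible
    vertical chord stays on the same side of the 0.20 mm dry-eye criterion as
    the nominal thickness, keeping a cohort's labelled prevalence equal in
    expectation to its requested dry-eye fraction: near-criterion menisci are
    rendered nearly uniform, while clearly-dry or clearly-normal bands may
    vary by up to 30 %.
    """
    w = h = 128
    cos_tilt = math.cos(math.radians(10.0))
    if thickness_mm < DRY_EYE_THRESHOLD_MM:
        # thickest chord <= 0.19 mm (one rasterization pixel of safety)
        mod_bound = max(0.0, 0.19 * cos_tilt / thickness_mm - 1.0)
    else:
        # thinnest chord >= 0.21 mm
        mod_bound = max(0.0, 1.0 - 0.21 / thickness_mm)
    return PhantomSpec(
        width_px=w,
        height_px=h,
        mm_per_px=0.01,
        eyelid_coeffs=(
            float(rng.uniform(0.002, 0.005)),
            float(rng.uniform(0.45 * w, 0.55 * w)),
            float(rng.uniform(0.70 * h, 0.80 * h)),
        ),
        meniscus_thickness_mm=thickness_mm,
        thickness_modulation=float(rng.uniform(0.0, min(0.3, mod_bound))),
        tilt_deg=float(rng.uniform(-10.0, 10.0)),
        noise_sd=0.02,
        illum_gradient=float(rng.uniform(0.0, 0.1)),
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n: int,
    spec_sampler: Callable[[np.random.Generator, float], PhantomSpec] | None = None,
    dry_eye_fraction: float = 0.3,
    seed: int = 0,
    threshold_mm: float = DRY_EYE_THRESHOLD_MM,
) -> list[AnnotatedSample]:
    """Generate ``n`` phantoms with a controlled dry-eye prevalence.

    Band thicknesses are drawn from a two-component mixture: with probability
    ``dry_eye_fraction`` from U(0.08, 0.18) mm (dry) and otherwise from
    U(0.215, 0.40) mm (normal).  The component gap — together with the
    modulation bound in :func:`default_spec_sampler` — keeps rasterization
    and tilt from flipping a sample across the 0.20 mm criterion, so the
    expected labelled prevalence equals ``dry_eye_fraction``; labels
    themselves are always derived from the rasterized ground truth, never
    from the component.
    """
    if n < 1:
        raise ValueError(f"cohort size must be at least 1, got {n}")
    if not (0 <= dry_eye_fraction <= 1):
        raise ValueError(f"dry_eye_fraction must lie in [0, 1], got {dry_eye_fraction}")
    sampler = spec_sampler if spec_sampler is not None else default_spec_sampler
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        dry = rng.random() < dry_eye_fraction
        thickness = float(
            rng.uniform(0.08, 0.18) if dry else rng.uniform(0.215, 0.40)
        )
        sample = generate_phantom(sampler(rng, thickness))
        sample.image.source_id = f"phantom-{i:04d}"
        sample.dry_eye_label = sample.true_tmh_mm < threshold_mm
        samples.append(sample)
    return samples


def write_dataset(
    samples: Sequence[AnnotatedSample],
    directory: str | Path,
    format: str = "mask-png",
) -> Path:
    """Write a cohort to disk and return the manifest path.

    Images become 8-bit grayscale PNGs; masks either 0/255 PNGs
    (``format="mask-png"``) or COCO-style polygon annotations
    (``format="coco-json"``).  The manifest records paths, ground-truth TMH,
    dry-eye labels and the calibration, and round-trips through the readers.
    """
    from . import io as tio  # local import: io depends on core only

    if format not in ("mask-png", "coco-json"):
        raise ValueError(f"unknown dataset format: {format!r}")
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    if format == "mask-png":
        (directory / "masks").mkdir(exist_ok=True)

    mm_per_px = samples[0].image.mm_per_px if samples else 0.01
    records = []
    for i, s in enumerate(samples):
        sid = s.image.source_id or f"phantom-{i:04d}"
        image_rel = f"images/{sid}.png"
        tio.write_image(directory / image_rel, s.image)
        rec = tio.ManifestRecord(
            source_id=sid,
            image_path=image_rel,
            true_tmh_mm=s.true_tmh_mm,
            manual_tmh_mm=s.true_tmh_mm,
            dry_eye_label=s.dry_eye_label,
        )
        if format == "mask-png":
            mask_rel = f"masks/{sid}.png"
            tio.write_mask(directory / mask_rel, s.mask)
            rec.mask_path = mask_rel
        else:
            rec.annotation_id = i
        records.append(rec)

    if format == "coco-json":
        tio.write_coco(
            directory / "annotations.json",
            [(rec.source_id, s.mask) for rec, s in zip(records, samples)],
        )
    manifest = tio.DatasetManifest(records=records, mm_per_px=mm_per_px)
    manifest_path = directory / "manifest.json"
    tio.save_manifest(manifest, manifest_path)
    return manifest_path
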