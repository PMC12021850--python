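"""Readers, writers and manifest handling.

Serialized coordinates are 0-based ``(row, col)`` with the row increasing
downward.  Masks are single-channel 0/255 PNGs; any nonzero value reads back
as foreground, so masks survive lossless editor round-trips.  Manifests are
JSON with a versioned schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .core import ManifestError, MeniscusMask, OcularImage

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "load_manifest",
    "save_manifest",
    "split_dataset",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_coco",
    "read_coco",
]

SCHEMA_VERSION = "1"
SPLIT_TAGS = ("train", "val", "test", "external")


@dataclass
class ManifestRecord:
    source_id: str
    image_path: str
    mask_path: str | None = None
    annotation_id: int | None = None
    true_tmh_mm: float | None = None
    manual_tmh_mm: float | None = None
    dry_eye_label: bool | None = None
    split: str | None = None


@dataclass
class DatasetManifest:
    """Pairs images with masks/annotations, labels and the calibration.

    ``root`` is the directory record paths are relative to; it is set on load
    and not serialized.
    """

    records: list[ManifestRecord]
    mm_per_px: float
    schema_version: str = SCHEMA_VERSION
    root: Path | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for i, rec in enumerate(self.records):
            if rec.source_id in seen:
                raise ManifestError(f"duplicate source_id {rec.source_id!r} (record {i})")
            seen.add(rec.source_id)
            if rec.split is not None and rec.split not in SPLIT_TAGS:
                raise ManifestError(
                    f"record {i} ({rec.source_id}): unknown split tag {rec.split!r}; "
                    f"expected one of {SPLIT_TAGS}"
                )
        if self.mm_per_px <= 0:
            raise ManifestError(f"mm_per_px must be positive, got {self.mm_per_px}")

    def resolve(self, relpath: str) -> Path:
        return (self.root / relpath) if self.root is not None else Path(relpath)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            records=[r for r in self.records if r.split == split],
            mm_per_px=self.mm_per_px,
            schema_version=self.schema_version,
            root=self.root,
        )


def save_manifest(manifest: DatasetManifest, path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": manifest.schema_version,
        "mm_per_px": manifest.mm_per_px,
        "records": [
            {k: v for k, v in asdict(rec).items() if v is not None}
            for rec in manifest.records
        ],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_manifest(path) -> DatasetManifest:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"malformed manifest JSON at {path}: {exc}") from exc
    try:
        records = [ManifestRecord(**rec) for rec in payload["records"]]
        manifest = DatasetManifest(
            records=records,
            mm_per_px=payload["mm_per_px"],
            schema_version=str(payload.get("schema_version", SCHEMA_VERSION)),
            root=path.parent,
        )
    except TypeError as exc:
        raise ManifestError(f"manifest schema violation at {path}: {exc}") from exc
    return manifest


def split_dataset(
    manifest: DatasetManifest,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetManifest:
    """Assign train/val/test tags at the given proportions, reproducibly.

    Counts are fixed by largest-remainder rounding (each differs from the
    exact fraction by less than one record); which record lands where is a
    seeded random permutation.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 nonnegative values summing to 1, got {fractions}")
    n = len(manifest.records)
    exact = fr * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    order = np.random.default_rng(seed).permutation(n)
    tags = np.empty(n, dtype=object)
    start = 0
    for tag, count in zip(("train", "val", "test"), counts):
        tags[order[start:start + count]] = tag
        start += count
    records = [
        ManifestRecord(**{**asdict(rec), "split": tags[i]})
        for i, rec in enumerate(manifest.records)
    ]
    return DatasetManifest(
        records=records,
        mm_per_px=manifest.mm_per_px,
        schema_version=manifest.schema_version,
        root=manifest.root,
    )


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_image(path, image: OcularImage) -> Path:
    path = Path(path)
    iio.imwrite(path, np.round(image.pixels * 255).astype(np.uint8))
    return path


def read_image(path, mm_per_px: float, source_id: str | None = None) -> OcularImage:
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if raw.ndim == 3:  # RGB(A): collapse to luminance-ish first channel mean
        raw = raw[..., :3].mean(axis=-1)
    return OcularImage.from_uint8(raw, mm_per_px, source_id or Path(path).stem)


def write_mask(path, mask: MeniscusMask) -> Path:
    path = Path(path)
    iio.imwrite(path, np.where(mask.pixels, 255, 0).astype(np.uint8))
    return path


def read_mask(path) -> MeniscusMask:
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw[..., :3].max(axis=-1)
    return MeniscusMask(raw != 0)


# ---------------------------------------------------------------------------
# COCO-style polygon annotations
# ---------------------------------------------------------------------------

def mask_to_polygons(mask: MeniscusMask) -> list[list[float]]:
    """Trace each foreground component into a flat [x0, y0, x1, y1, ...] ring.

    Contours are taken at the 0.5 iso-level of the padded raster, so vertices
    sit on the half-pixel boundary around foreground pixel centres;
    re-rasterizing recovers the original mask to within the boundary pixels.
    """
    padded = np.pad(mask.pixels.astype(float), 1)
    polygons = []
    for contour in measure.find_contours(padded, 0.5):
        ring = contour - 1.0  # undo the pad
        xy = np.empty(ring.shape[0] * 2)
        xy[0::2] = ring[:, 1]  # x = col
        xy[1::2] = ring[:, 0]  # y = row
        polygons.append([round(float(v), 3) for v in xy])
    return polygons


def polygons_to_mask(polygons: Sequence[Sequence[float]], shape: tuple[int, int]) -> MeniscusMask:
    out = np.zeros(shape, dtype=bool)
    for ring in polygons:
        xy = np.asarray(ring, dtype=float)
        rr, cc = draw_polygon(xy[1::2], xy[0::2], shape=shape)
        out[rr, cc] = True
    return MeniscusMask(out)


def write_coco(path, entries: Sequence[tuple[str, MeniscusMask]]) -> Path:
    """Write COCO-style annotations: one image and one annotation per mask."""
    images, annotations = [], []
    for i, (source_id, mask) in enumerate(entries):
        h, w = mask.shape
        images.append({"id": i, "file_name": f"{source_id}.png", "height": h, "width": w})
        annotations.append(
            {
                "id": i,
                "image_id": i,
                "category_id": 1,
                "segmentation": mask_to_polygons(mask),
                "area": mask.area,
                "iscrowd": 0,
            }
        )
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "tear_meniscus"}],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_coco(path) -> dict[int, MeniscusMask]:
    """Rasterize COCO polygon annotations back into masks, keyed by annotation id."""
    payload = json.loads(Path(path).read_text())
    shapes = {img["id"]: (img["height"], img["width"]) for img in payload["images"]}
    masks = {}
    for ann in payload["annotations"]:
        masks[ann["id"]] = polygons_to_mask(ann["segmentation"], shapes[ann["image_id"]])
    return masks
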