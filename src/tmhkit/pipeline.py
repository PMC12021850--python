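"""End-to-end pipeline: simulate -> segment -> measure -> evaluate.

All randomness flows from one global seed: stage seeds are derived as
``(seed + offset) % 2**31`` with fixed offsets (cohort +0, split +1,
training +2), so a rerun with the same configuration reproduces every
artifact byte-for-byte (PNG encoding settings are fixed by the writer).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as tio
from .core import DRY_EYE_THRESHOLD_MM
from .evaluation import evaluate
from .metry import measure_batch
from .phantom import generate_cohort, write_dataset
from .segmentation import BaselineSegmenter, TrainConfig, train_segmenter

logger = logging.getLogger("tmhkit.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artifacts are flagged in the log."""


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str
    n_phantoms: int = 100
    dry_eye_fraction: float = 0.3
    segmenter: str = "baseline"  # "baseline" or "trained"
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    threshold_mm: float = DRY_EYE_THRESHOLD_MM
    seed: int = 0
    log_level: str = "INFO"
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        self.validate()

    def validate(self) -> None:
        if not self.out_dir:
            raise ValueError("config missing required field: out_dir")
        if self.n_phantoms < 10:
            raise ValueError(f"n_phantoms must be at least 10, got {self.n_phantoms}")
        if self.segmenter not in ("baseline", "trained"):
            raise ValueError(f"segmenter must be 'baseline' or 'trained', got {self.segmenter!r}")
        if not (0 <= self.dry_eye_fraction <= 1):
            raise ValueError(f"dry_eye_fraction must lie in [0, 1], got {self.dry_eye_fraction}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"pipeline config must be a mapping, got {type(raw).__name__}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid pipeline config: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d


def _stage_seed(seed: int, offset: int) -> int:
    return (seed + offset) % 2**31


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the paths of the artifacts written.

    Artifacts under ``out_dir``: ``dataset/`` (images, masks, manifest with
    split tags), ``model.npz`` (+ sidecar, trained runs only),
    ``measurements.csv``, ``report.json``, ``roc.csv`` and
    ``run_metadata.json``.  Any stage failure raises :class:`PipelineError`.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict[str, str] = {}

    try:
        logger.info("stage simulate: n=%d dry_eye_fraction=%.2f", config.n_phantoms,
                    config.dry_eye_fraction)
        samples = generate_cohort(
            config.n_phantoms,
            dry_eye_fraction=config.dry_eye_fraction,
            seed=_stage_seed(config.seed, 0),
            threshold_mm=config.threshold_mm,
        )
        by_id = {s.image.source_id: s for s in samples}
        manifest_path = write_dataset(samples, out / "dataset", format="mask-png")
        manifest = tio.load_manifest(manifest_path)
        manifest = tio.split_dataset(manifest, config.fractions, seed=_stage_seed(config.seed, 1))
        tio.save_manifest(manifest, manifest_path)
        artifacts["manifest"] = str(manifest_path)
        logger.info("stage simulate: wrote %d samples -> %s", len(samples), manifest_path)

        if config.segmenter == "trained":
            train_cfg = TrainConfig(**{**asdict(config.train), "seed": _stage_seed(config.seed, 2)})
            train_split = [by_id[r.source_id] for r in manifest.subset("train").records]
            val_split = [by_id[r.source_id] for r in manifest.subset("val").records]
            logger.info("stage train: %d train / %d val, max_epochs=%d",
                        len(train_split), len(val_split), train_cfg.max_epochs)
            segmenter, log = train_segmenter(train_split, val_split, train_cfg)
            model_path = out / "model.npz"
            segmenter.save(model_path, config=train_cfg, log=log)
            artifacts["model"] = str(model_path)
            logger.info("stage train: best val IoU %.4f at epoch %d",
                        log.best_val_iou, log.best_epoch)
        else:
            segmenter = BaselineSegmenter()
            logger.info("stage segment: using the classical baseline segmenter")

        test = manifest.subset("test")
        logger.info("stage measure: %d test images", len(test.records))
        table = measure_batch(test, segmenter, manifest.mm_per_px, config.threshold_mm)
        measurements_path = out / "measurements.csv"
        table.to_csv(measurements_path, index=False)
        artifacts["measurements"] = str(measurements_path)
        n_flagged = int((table["flag"] != "").sum())
        if n_flagged:
            logger.warning("stage measure: %d of %d rows flagged", n_flagged, len(table))

        logger.info("stage evaluate: threshold %.2f mm", config.threshold_mm)
        pred = [segmenter.predict(by_id[r.source_id].image) for r in test.records]
        truth = [by_id[r.source_id].mask for r in test.records]
        manual = [by_id[r.source_id].true_tmh_mm for r in test.records]
        report = evaluate(pred, truth, manual, manifest.mm_per_px, config.threshold_mm)
        report_path = out / "report.json"
        report.to_json(report_path)
        report.roc.as_table().to_csv(out / "roc.csv", index=False)
        artifacts["report"] = str(report_path)
        artifacts["roc"] = str(out / "roc.csv")
        logger.info("stage evaluate: mean IoU %.4f, AUC %.4f, R^2 %.4f",
                    report.mean_iou, report.roc.auc, report.regression.r_squared)
    except Exception as exc:
        logger.error("pipeline failed: %s; artifacts so far: %s", exc, sorted(artifacts))
        raise PipelineError(str(exc)) from exc

    metadata = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "started_unix": round(t0, 3),
        "elapsed_s": round(time.time() - t0, 3),
        "artifacts": artifacts,
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    artifacts["run_metadata"] = str(out / "run_metadata.json")
    return artifacts
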