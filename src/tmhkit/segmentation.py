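"""Meniscus segmentation: a classical baseline and a small trainable CNN.

Two segmenters sit behind one ``predict(image) -> MeniscusMask`` contract:

``segment_baseline``
    A deterministic classical pipeline — Otsu threshold estimated on the
    lower half of the image, 3x3 morphological opening, and retention of the
    largest connected component.  It has no parameters to fit and anchors
    the measurement/evaluation stack independently of any training.

``ConvSegmenter`` / ``train_segmenter``
    A fully convolutional pixel classifier: one 5x5 convolution with ReLU
    feature maps followed by a 1x1 convolution and a sigmoid, ~220
    parameters, implemented directly in numpy.  It is trained with
    minibatch SGD (momentum 0.9, weight decay 5e-4, initial learning rate
    1e-3, learning rate multiplied by 0.2 every 40 epochs) under pixelwise
    binary cross-entropy, with the checkpoint taken at the epoch of peak
    validation mean IoU rather than the final epoch.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import MeniscusMask, OcularImage
from .evaluation import iou
from .metry import largest_component

__all__ = [
    "BaselineConfig",
    "segment_baseline",
    "BaselineSegmenter",
    "TrainConfig",
    "TrainingLog",
    "ConvSegmenter",
    "train_segmenter",
    "predict",
]


# ---------------------------------------------------------------------------
# classical baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineConfig:
    """Parameters of the classical thresholding pipeline.

    ``otsu_lower_fraction`` is the fraction of image rows, counted from the
    bottom, used to estimate the Otsu threshold; the threshold is then
    applied to the whole frame.  The meniscus sits along the lower eyelid,
    so restricting the estimate to the lower half keeps bright upper-field
    structures from skewing it.
    """

    otsu_lower_fraction: float = 0.5
    opening_size: int = 3


def segment_baseline(image: OcularImage, config: BaselineConfig | None = None) -> MeniscusMask:
    """Threshold + opening + largest component.  Pure function of its inputs.

    A uniform image (no Otsu threshold exists) or an image where nothing
    survives the morphology yields an *empty mask*, not an error: downstream
    batch drivers treat emptiness as "no meniscus found".
    """
    cfg = config or BaselineConfig()
    pixels = image.pixels
    h = pixels.shape[0]
    lower = pixels[int(h * (1 - cfg.otsu_lower_fraction)):]
    if np.ptp(lower) == 0:
        return MeniscusMask(np.zeros(pixels.shape, dtype=bool))
    thr = threshold_otsu(lower)
    binary = pixels > thr
    if cfg.opening_size > 1:
        footprint = np.ones((cfg.opening_size, cfg.opening_size), dtype=bool)
        binary = ndimage.binary_opening(binary, structure=footprint)
    if not binary.any():
        return MeniscusMask(binary)
    return largest_component(binary)


class BaselineSegmenter:
    """Object adapter so the baseline satisfies the ``predict`` contract."""

    def __init__(self, config: BaselineConfig | None = None):
        self.config = config or BaselineConfig()

    def predict(self, image: OcularImage) -> MeniscusMask:
        return segment_baseline(image, self.config)


# ---------------------------------------------------------------------------
# trainable segmenter
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """SGD training protocol for the trainable segmenter.

    Defaults follow the optimisation recipe used for the full-scale model:
    learning rate 0.001, momentum 0.9, weight decay 0.0005, and a step
    schedule multiplying the learning rate by 0.2 every 40 epochs.
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    lr_step_epochs: int = 40
    lr_factor: float = 0.2
    max_epochs: int = 200
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_factor < 1):
            raise ValueError(f"lr_factor must lie in (0, 1), got {self.lr_factor}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be at least 1, got {self.max_epochs}")
        if self.lr_step_epochs < 1:
            raise ValueError(f"lr_step_epochs must be at least 1, got {self.lr_step_epochs}")

    def lr_at(self, epoch: int) -> float:
        """Schedule: lr * factor ** floor(epoch / step), epoch 0-based."""
        return self.learning_rate * self.lr_factor ** (epoch // self.lr_step_epochs)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_iou: float


@dataclass
class TrainingLog:
    """Per-epoch history plus the checkpoint bookkeeping.

    ``best_epoch`` is the *first* epoch attaining the maximum validation mean
    IoU; the trained segmenter returned by the harness carries the parameters
    saved at that epoch, not the final one.
    """

    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_val_iou: float = -1.0

    def to_dict(self) -> dict:
        return {
            "epochs": [asdict(e) for e in self.epochs],
            "best_epoch": self.best_epoch,
            "best_val_iou": self.best_val_iou,
        }


class ConvSegmenter:
    """Two-layer fully convolutional pixel classifier in plain numpy.

    Architecture: 5x5 conv (1 -> n_filters channels, zero padding 2) -> ReLU
    -> 1x1 conv -> sigmoid, thresholded at 0.5.  Being fully convolutional it
    accepts any image at least 5 px on a side.  Inputs are centred at 0.5 so
    the background is slightly negative and the bright band positive.
    """

    KERNEL = 5

    def __init__(self, n_filters: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        k = self.KERNEL
        self.n_filters = n_filters
        # He-style initialisation for the ReLU layer
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(n_filters, k, k))
        self.b1 = np.zeros(n_filters)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / n_filters), size=n_filters)
        self.b2 = 0.0
        self._velocity = {name: np.zeros_like(p) for name, p in self._params().items()}

    def _params(self) -> dict:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": np.atleast_1d(self.b2)}

    @property
    def n_parameters(self) -> int:
        return sum(np.size(p) for p in self._params().values())

    # -- forward / backward -------------------------------------------------

    def _windows(self, pixels: np.ndarray) -> np.ndarray:
        pad = self.KERNEL // 2
        x = np.pad(pixels - 0.5, pad, mode="edge")
        return sliding_window_view(x, (self.KERNEL, self.KERNEL))

    def _forward(self, pixels: np.ndarray):
        win = self._windows(pixels)
        pre = np.tensordot(win, self.w1, axes=([2, 3], [1, 2])) + self.b1
        act = np.maximum(pre, 0.0)
        logit = act @ self.w2 + self.b2
        prob = 1.0 / (1.0 + np.exp(-logit))
        return win, pre, act, prob

    def predict_proba(self, image: OcularImage) -> np.ndarray:
        """Per-pixel foreground probability map in [0, 1]."""
        if min(image.shape) < self.KERNEL:
            raise ValueError(
                f"image {image.shape} smaller than the {self.KERNEL}x{self.KERNEL} kernel"
            )
        return self._forward(image.pixels)[3]

    def predict(self, image: OcularImage) -> MeniscusMask:
        """Deterministic boolean mask: probability > 0.5."""
        return MeniscusMask(self.predict_proba(image) > 0.5)

    def _loss_and_grads(self, pixels: np.ndarray, target: np.ndarray):
        win, pre, act, prob = self._forward(pixels)
        y = target.astype(float)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        g = (prob - y) / y.size  # d(mean BCE)/d logit
        grads = {
            "w2": np.tensordot(act, g, axes=([0, 1], [0, 1])),
            "b2": np.atleast_1d(g.sum()),
        }
        dact = g[..., None] * self.w2
        dpre = dact * (pre > 0)
        grads["w1"] = np.tensordot(dpre, win, axes=([0, 1], [0, 1]))
        grads["b1"] = dpre.sum(axis=(0, 1))
        return loss, grads

    def sgd_step(self, batch, lr: float, momentum: float, weight_decay: float) -> float:
        """One SGD-with-momentum update on a batch of (pixels, target) pairs.

        Gradients are averaged over the batch; weight decay is added to the
        gradient before the momentum update (the standard SGD formulation).
        """
        total = 0.0
        acc = {name: np.zeros_like(p) for name, p in self._params().items()}
        for pixels, target in batch:
            loss, grads = self._loss_and_grads(pixels, target)
            total += loss
            for name in acc:
                acc[name] += grads[name] / len(batch)
        params = self._params()
        for name, p in params.items():
            g = acc[name] + weight_decay * p
            self._velocity[name] = momentum * self._velocity[name] + g
            p -= lr * self._velocity[name]
        self.b2 = float(params["b2"][0])
        return total / len(batch)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "n_filters": self.n_filters,
            "w1": self.w1.copy(),
            "b1": self.b1.copy(),
            "w2": self.w2.copy(),
            "b2": self.b2,
        }

    def load_state_dict(self, state: dict) -> None:
        self.n_filters = int(state["n_filters"])
        self.w1 = np.array(state["w1"], dtype=float)
        self.b1 = np.array(state["b1"], dtype=float)
        self.w2 = np.array(state["w2"], dtype=float)
        self.b2 = float(state["b2"])
        self._velocity = {name: np.zeros_like(p) for name, p in self._params().items()}

    def save(self, path, config: TrainConfig | None = None, log: TrainingLog | None = None) -> None:
        """Serialize parameters (.npz) with a JSON sidecar for config + log."""
        path = Path(path)
        np.savez(path, **{k: np.asarray(v) for k, v in self.state_dict().items()})
        sidecar = {"train_config": asdict(config) if config else None,
                   "training_log": log.to_dict() if log else None}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ConvSegmenter":
        with np.load(path) as data:
            state = {k: data[k] for k in data.files}
        model = cls(n_filters=int(state["n_filters"]))
        model.load_state_dict(state)
        return model


def validation_mean_iou(segmenter, samples) -> float:
    """Mean per-image IoU of predictions against ground-truth masks.

    Uses the shared empty-mask convention: both empty -> 1.0, one empty -> 0.
    """
    return float(np.mean([iou(segmenter.predict(s.image), s.mask) for s in samples]))


def train_segmenter(
    train: Sequence,
    val: Sequence,
    config: TrainConfig | None = None,
) -> tuple[ConvSegmenter, TrainingLog]:
    """Train a :class:`ConvSegmenter` on annotated samples.

    Shuffles the training set each epoch, applies the step learning-rate
    schedule exactly (``lr * factor ** floor(epoch / step)``), records the
    validation mean IoU after every epoch, and returns the model restored to
    the parameters of the first epoch attaining the peak validation IoU.
    Aborts with a diagnostic if the loss becomes non-finite.
    """
    cfg = config or TrainConfig()
    if len(train) == 0 or len(val) == 0:
        raise ValueError(
            f"train and val must be nonempty, got {len(train)} train / {len(val)} val"
        )
    shape = train[0].image.shape
    for s in list(train) + list(val):
        if s.image.shape != shape:
            raise ValueError(
                f"all samples must share dimensions; expected {shape}, got {s.image.shape}"
            )

    rng = np.random.default_rng(cfg.seed)
    model = ConvSegmenter(seed=int(rng.integers(2**31)))
    data = [(s.image.pixels, s.mask.pixels) for s in train]
    log = TrainingLog()
    best_state = model.state_dict()

    for epoch in range(cfg.max_epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(data), cfg.batch_size):
            batch = [data[i] for i in order[start:start + cfg.batch_size]]
            losses.append(model.sgd_step(batch, lr, cfg.momentum, cfg.weight_decay))
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"training diverged: non-finite loss {train_loss} at epoch {epoch} "
                f"(lr={lr:g}); consider lowering the learning rate"
            )
        val_iou = validation_mean_iou(model, val)
        log.epochs.append(EpochRecord(epoch=epoch, lr=lr, train_loss=train_loss, val_iou=val_iou))
        if val_iou > log.best_val_iou:
            log.best_val_iou = val_iou
            log.best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return model, log


def predict(segmenter, image: OcularImage) -> MeniscusMask:
    """Functional façade over the segmenter's ``predict`` method."""
    return segmenter.predict(image)
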