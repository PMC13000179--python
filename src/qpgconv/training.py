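"""Hybrid training loop and segmentation metrics.

Each optimization step regenerates the quantum-managed kernels from the
current circuit angles, runs the forward pass, and backpropagates the loss
through the classical layers and the statevector simulator alike, so one
Adam update moves classical weights and rotation angles together.  Defaults
follow the reference recipe: Adam, learning rate 0.001, weight decay 5e-4,
batch size 8, 20 epochs, no learning-rate scheduler; circuit angles are
initialised uniformly on [0, 1) and classical weights by fan-in
variance scaling, never all-zero.

Evaluation is sample-wise: IoU_i = |A ∩ B| / |A ∪ B| and
DSC_i = 2|A ∩ B| / (|A| + |B|) per test image, then mean and (population)
standard deviation across samples, so small targets weigh the same as large
ones.  The empty-mask convention: both masks empty -> 1, exactly one empty
-> 0.  The test-set metrics of the best epoch are retained as the run's
result.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tensor import Adam, Tensor
from .models import MiniUNext

__all__ = ["TrainConfig", "MetricsReport", "History", "iou", "dsc",
           "aggregate", "evaluate", "train", "bce_loss", "dice_loss",
           "segmentation_loss", "write_metrics_csv", "write_summary_json"]

_EPS = 1e-7
LOSSES = ("bce", "dice", "bce_plus_dice")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    batch_size: int = 8
    epochs: int = 20
    seed: int = 0
    loss: str = "bce_plus_dice"
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {LOSSES}")


@dataclass(frozen=True)
class MetricsReport:
    """Per-sample IoU/DSC with their mean and population std."""

    iou: np.ndarray = field(repr=False)
    dsc: np.ndarray = field(repr=False)

    @property
    def iou_mean(self) -> float:
        return float(self.iou.mean())

    @property
    def iou_std(self) -> float:
        return float(self.iou.std())

    @property
    def dsc_mean(self) -> float:
        return float(self.dsc.mean())

    @property
    def dsc_std(self) -> float:
        return float(self.dsc.std())

    def summary(self) -> dict:
        return {"n_samples": int(self.iou.size),
                "iou_mean": self.iou_mean, "iou_std": self.iou_std,
                "dsc_mean": self.dsc_mean, "dsc_std": self.dsc_std}


@dataclass
class History:
    """Step losses, per-epoch records, and the best-epoch test metrics."""

    step_losses: list = field(default_factory=list)
    epochs: list = field(default_factory=list)        # dicts per epoch
    best_epoch: int = -1
    best_metrics: MetricsReport | None = None


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _as_binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Intersection over union of two binary masks (both empty -> 1)."""
    a, b = _as_binary(pred_mask), _as_binary(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dsc(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks (both empty -> 1)."""
    a, b = _as_binary(pred_mask), _as_binary(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def aggregate(pred_masks, true_masks) -> MetricsReport:
    """Sample-wise IoU/DSC over paired mask collections, equally weighted."""
    preds, trues = list(pred_masks), list(true_masks)
    if not preds or len(preds) != len(trues):
        raise ValueError("need one or more prediction/truth mask pairs")
    ious = np.array([iou(p, t) for p, t in zip(preds, trues)])
    dscs = np.array([dsc(p, t) for p, t in zip(preds, trues)])
    return MetricsReport(iou=ious, dsc=dscs)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Binary cross-entropy on probabilities (mean over all pixels)."""
    one = 1.0
    return -(target * (pred + _EPS).log()
             + (one - target) * (one - pred + _EPS).log()).mean()


def dice_loss(pred: Tensor, target: Tensor) -> Tensor:
    """Soft Dice loss with +1 smoothing, over the whole batch."""
    inter = (pred * target).sum()
    return 1.0 - (2.0 * inter + 1.0) / (pred.sum() + target.sum() + 1.0)


def segmentation_loss(pred: Tensor, target: Tensor, kind: str) -> Tensor:
    if kind == "bce":
        return bce_loss(pred, target)
    if kind == "dice":
        return dice_loss(pred, target)
    return bce_loss(pred, target) + dice_loss(pred, target)


# ---------------------------------------------------------------------------
# evaluation and training
# ---------------------------------------------------------------------------

def _forward_batched(model, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
    outs = []
    for start in range(0, images.shape[0], batch_size):
        outs.append(model(Tensor(images[start:start + batch_size])).data)
    return np.concatenate(outs, axis=0)


def evaluate(model: MiniUNext, images: np.ndarray, masks: np.ndarray,
             threshold: float = 0.5) -> MetricsReport:
    """Binarize predictions at `threshold` and report sample-wise metrics."""
    probs = _forward_batched(model, images)
    preds = probs[:, 0] >= threshold
    return aggregate(list(preds), list(masks[:, 0].astype(bool)))


def train(model: MiniUNext, train_images: np.ndarray, train_masks: np.ndarray,
          test_images: np.ndarray | None = None,
          test_masks: np.ndarray | None = None,
          config: TrainConfig = TrainConfig(),
          log=None) -> History:
    """Run the hybrid loop; returns the loss/metric history.

    `train_images`/`train_masks` are (n, 1, H, W) float arrays; masks are
    {0,1}-valued.  When a test split is given, it is evaluated after every
    epoch and the best mean-DSC epoch is retained in `history.best_metrics`.
    Identical configs (same seed) give bitwise-identical runs.
    """
    n = train_images.shape[0]
    if n == 0:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    history = History()
    best_dsc = -1.0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(train_images[idx])
            yb = Tensor(train_masks[idx])
            optimizer.zero_grad()
            pred = model(xb)
            loss = segmentation_loss(pred, yb, config.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch} step "
                    f"{start // config.batch_size}; aborting")
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
            history.step_losses.append(value)
            if log is not None:
                log(f"epoch={epoch} step={start // config.batch_size} "
                    f"loss={value:.5f}")
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if test_images is not None and test_images.shape[0]:
            report = evaluate(model, test_images, test_masks, config.threshold)
            record.update(test_iou=report.iou_mean, test_dsc=report.dsc_mean)
            if report.dsc_mean > best_dsc:
                best_dsc = report.dsc_mean
                history.best_epoch = epoch
                history.best_metrics = report
        history.epochs.append(record)
        if log is not None:
            log("epoch summary " + json.dumps(record))
    return history


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_metrics_csv(report: MetricsReport, path) -> None:
    """One row per sample: index, IoU_i, DSC_i."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "iou", "dsc"])
        for i, (a, b) in enumerate(zip(report.iou, report.dsc)):
            writer.writerow([i, f"{a:.6f}", f"{b:.6f}"])


def write_summary_json(report: MetricsReport, path) -> None:
    Path(path).write_text(json.dumps(report.summary(), indent=2) + "\n")


def write_history_csv(history: History, path) -> None:
    fields = ["epoch", "train_loss", "test_iou", "test_dsc"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for record in history.epochs:
            writer.writerow({k: record.get(k, "") for k in fields})
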