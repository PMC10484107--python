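"""Training and evaluation of the seed-crop classifier.

Training follows the regime the classifier is tuned for: Adam, batch size
32, learning rate 0.001, a fixed epoch budget with no early stopping by
default, and a seeded 4:1 train:test split upstream.  Evaluation reports
accuracy, precision, recall and F1 as percentages from the confusion
counts, with *defective* as the positive class (the operationally
important one when sorting seed).

Metric definitions (counts TP/TN/FP/FN, reported x100):

    A  = (TP + TN) / (TP + TN + FN + FP)
    P  = TP / (TP + FP)
    R  = TP / (TP + FN)
    F1 = 2 P R / (P + R)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .arch import SeedClassifier
from .synthgen import CLASSES, DEFECTIVE, GOOD

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 0.001
    epochs: int = 100
    optimizer: str = "adam"  # or "sgd"
    split_ratio: float = 0.8
    rng_seed: int = 0
    augment_flip: bool = False
    #: optional test-accuracy level at which training stops early (fraction);
    #: None reproduces the fixed-epoch regime
    stop_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / precision / recall / F1, each in percent."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def confusion(labels: Sequence[str], predictions: Sequence[str]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with ``defective`` as the positive class."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    tp = tn = fp = fn = 0
    for t, p in zip(labels, predictions):
        if t not in CLASSES or p not in CLASSES:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if t == DEFECTIVE:
            if p == DEFECTIVE:
                tp += 1
            else:
                fn += 1
        else:
            if p == DEFECTIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 (percent) from confusion counts.

    Undefined ratios (zero denominators) are reported as 0 with a logged
    warning rather than NaN.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")

    def safe(num: float, den: float, what: str) -> float:
        if den == 0:
            logger.warning("metrics: %s undefined (zero denominator); reporting 0", what)
            return 0.0
        return num / den

    a = (counts.TP + counts.TN) / counts.total
    p = safe(counts.TP, counts.TP + counts.FP, "precision")
    r = safe(counts.TP, counts.TP + counts.FN, "recall")
    f1 = safe(2 * p * r, p + r, "F1")
    return MetricsReport(
        accuracy=100.0 * a, precision=100.0 * p, recall=100.0 * r, f1=100.0 * f1
    )


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------


def pad_to_square(image: np.ndarray, fill: int | None = None) -> np.ndarray:
    """Pad an H x W x 3 array to a centred square before resizing."""
    h, w = image.shape[:2]
    if h == w:
        return image
    side = max(h, w)
    if fill is None:
        # use the median border intensity so padding blends with background
        border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
        fill = int(np.median(border))
    out = np.full((side, side, 3), fill, dtype=image.dtype)
    y0 = (side - h) // 2
    x0 = (side - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = image
    return out


def prepare_crop(image: np.ndarray, size: int) -> np.ndarray:
    """Pad to square, bilinear-resize to ``size`` and scale to [0, 1] CHW."""
    sq = pad_to_square(np.asarray(image))
    if sq.shape[0] != size:
        sq = np.asarray(
            Image.fromarray(sq.astype(np.uint8)).resize((size, size), Image.BILINEAR)
        )
    return (sq.astype(np.float32) / 255.0).transpose(2, 0, 1)


def load_manifest(manifest: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    if not {"path", "label"}.issubset(manifest.columns):
        raise ValueError("manifest needs 'path' and 'label' columns")
    return manifest.reset_index(drop=True)


def load_crop_batch(manifest: pd.DataFrame, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load every crop in a manifest as an (N, 3, size, size) float batch."""
    xs = np.stack(
        [prepare_crop(np.asarray(Image.open(p).convert("RGB")), size) for p in manifest["path"]]
    )
    return xs, manifest["label"].to_numpy()


def arrays_to_batch(X: np.ndarray, size: int) -> np.ndarray:
    """Prepare an (N, H, W, 3) uint8 stack for the classifier."""
    return np.stack([prepare_crop(x, size) for x in X])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _class_indices(labels: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(np.array(CLASSES), labels)
    lut = {c: i for i, c in enumerate(CLASSES)}
    return np.array([lut[l] for l in labels], dtype=np.int64)


def _accuracy(model: SeedClassifier, X: np.ndarray, y_idx: np.ndarray) -> float:
    proba = model.predict_proba(X)
    return float((proba.argmax(axis=1) == y_idx).mean())


def train(
    model: SeedClassifier,
    train_manifest: pd.DataFrame | str | Path,
    config: TrainConfig,
    test_manifest: pd.DataFrame | str | Path | None = None,
    train_arrays: tuple[np.ndarray, np.ndarray] | None = None,
    test_arrays: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Train in place; return a history frame (epoch, loss, test_accuracy).

    Data come either from ``path,label`` manifests or directly from
    ``(X, y)`` array pairs (H x W x 3 uint8 stacks with class-name labels).
    With ``config.stop_accuracy`` set, training ends at the first epoch
    whose test accuracy reaches that level; the epoch count is always the
    upper bound.  Without a test set the per-epoch accuracy column reports
    training accuracy.
    """
    size = model.config.input_size
    if train_arrays is not None:
        X, y = arrays_to_batch(train_arrays[0], size), np.asarray(train_arrays[1])
    else:
        X, y = load_crop_batch(load_manifest(train_manifest), size)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if config.batch_size > X.shape[0]:
        raise ValueError("batch_size exceeds the training-set size")
    y_idx = _class_indices(y)

    Xt = yt_idx = None
    if test_arrays is not None:
        Xt, yt = arrays_to_batch(test_arrays[0], size), np.asarray(test_arrays[1])
        yt_idx = _class_indices(yt)
    elif test_manifest is not None:
        Xt, yt = load_crop_batch(load_manifest(test_manifest), size)
        yt_idx = _class_indices(yt)

    params = model.params()
    if config.optimizer == "adam":
        opt: nn.Optimizer = nn.Adam(params, lr=config.learning_rate)
    else:
        opt = nn.SGD(params, lr=config.learning_rate)

    rng = np.random.default_rng(config.rng_seed)
    n = X.shape[0]
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y_idx[idx]
            if config.augment_flip:
                flip_h = rng.random(len(idx)) < 0.5
                flip_v = rng.random(len(idx)) < 0.5
                xb = xb.copy()
                xb[flip_h] = xb[flip_h, :, :, ::-1]
                xb[flip_v] = xb[flip_v, :, ::-1, :]
            opt.zero_grad()
            logits = model.forward(xb, training=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        if Xt is not None:
            acc = _accuracy(model, Xt, yt_idx)
        else:
            acc = _accuracy(model, X, y_idx)
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "test_accuracy": acc}
        )
        logger.info("epoch %d: loss %.4f, accuracy %.4f", epoch, history[-1]["loss"], acc)
        if config.stop_accuracy is not None and acc >= config.stop_accuracy:
            logger.info("reached stop accuracy %.3f at epoch %d", config.stop_accuracy, epoch)
            break
    return pd.DataFrame(history, columns=["epoch", "loss", "test_accuracy"])


def predict(
    model: SeedClassifier, X: np.ndarray, classes: Sequence[str] = CLASSES
) -> tuple[np.ndarray, np.ndarray]:
    """Class names and confidences (max softmax) for prepared CHW batches."""
    proba = model.predict_proba(X)
    idx = proba.argmax(axis=1)
    return np.asarray(classes)[idx], proba.max(axis=1)


def evaluate(
    model: SeedClassifier,
    test_manifest: pd.DataFrame | str | Path | None = None,
    test_arrays: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[MetricsReport, ConfusionCounts, pd.DataFrame]:
    """Score a manifest (or array pair): metrics, confusion, per-sample table."""
    size = model.config.input_size
    if test_arrays is not None:
        X, y = arrays_to_batch(test_arrays[0], size), np.asarray(test_arrays[1])
        paths = [f"array[{i}]" for i in range(len(y))]
    else:
        man = load_manifest(test_manifest)
        if man.empty:
            raise ValueError("empty test manifest")
        X, y = load_crop_batch(man, size)
        paths = man["path"].tolist()
    pred, conf = predict(model, X)
    counts = confusion(list(y), list(pred))
    table = pd.DataFrame(
        {"path": paths, "true": y, "predicted": pred, "confidence": conf}
    )
    return metrics(counts), counts, table
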