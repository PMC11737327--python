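"""Dataset splitting, the training loop, and evaluation metrics.

The benchmark protocol is a single stratified train/validation/test split in
the ratio 6:2:2, minibatch SGD with momentum for at most 60 epochs, and
selection of the epoch snapshot with the best validation accuracy. The
positive class for recall/precision/F1 is "case".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import CASE, ValidationError
from .encoding import GenotypeImage
from .nn import ConvNet, HyperParams, ModelConfig, TrainingDiverged

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    """Stratified train:val:test ratios (default 6:2:2) and a seed."""

    train: float = 0.6
    val: float = 0.2
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValidationError("split ratios must sum to 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ValidationError("all split ratios must be positive")


def split_dataset(labels: np.ndarray, spec: SplitSpec):
    """Return disjoint, exhaustive (train_idx, val_idx, test_idx).

    Stratified per class: within each label the samples are shuffled with the
    spec's seed, then sliced so each partition holds its nominal share of the
    class (rounded). Same seed -> identical partitions.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_test = int(round(spec.test * n))
        n_val = int(round(spec.val * n))
        n_train = n - n_val - n_test
        if min(n_train, n_val, n_test) < 1:
            raise ValidationError(
                f"class {cls} has only {n} samples; cannot fill all three partitions"
            )
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )


def stack_images(images: Sequence[GenotypeImage]):
    """Images -> (x, y): float32 pixels scaled by 1/255, channels-last."""
    arrs = []
    for im in images:
        px = im.pixels.astype(np.float32) / 255.0
        if px.ndim == 2:
            px = px[..., None]
        arrs.append(px)
    x = np.stack(arrs)
    y = np.array([im.label for im in images], dtype=np.int64)
    return x, y


@dataclass
class TrainResult:
    model: ConvNet
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0
    best_val_accuracy: float = 0.0


def train(
    model: ConvNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> TrainResult:
    """SGD-with-momentum training with best-validation-epoch selection.

    Uses the model's HyperParams (learning rate, momentum, L2) and
    ModelConfig (batch size, max epochs, seed). The returned model carries
    the parameter snapshot of the epoch with the highest validation
    accuracy. Raises TrainingDiverged if the loss becomes non-finite.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValidationError("training and validation sets must be non-empty")
    hp, cfg = model.hp, model.config
    rng = np.random.default_rng(cfg.seed + 1)
    dropout_rng = np.random.default_rng(cfg.seed + 2)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    best_params = model.clone_params()
    best_val, best_epoch = -1.0, 0
    history: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            batch = order[s : s + cfg.batch_size]
            loss, grads = model.loss_and_grads(x_train[batch], y_train[batch], dropout_rng)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"loss became {loss} at epoch {epoch}")
            losses.append(loss)
            for k, g in grads.items():
                velocity[k] = hp.momentum * velocity[k] - hp.learning_rate * g
                model.params[k] += velocity[k]
        val_acc = float((model.predict(x_val) == y_val).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
            best_params = model.clone_params()
        logger.debug("epoch %d: loss %.4f val_acc %.4f", epoch, history[-1]["train_loss"], val_acc)

    model.set_params(best_params)
    return TrainResult(model=model, history=history, best_epoch=best_epoch, best_val_accuracy=best_val)


@dataclass
class EvalMetrics:
    """Confusion counts and derived scores; positive class = case."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    recall: float
    precision: float
    f1: float


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_pred == CASE) & (y_true == CASE)).sum())
    fp = int(((y_pred == CASE) & (y_true != CASE)).sum())
    fn = int(((y_pred != CASE) & (y_true == CASE)).sum())
    tn = int(((y_pred != CASE) & (y_true != CASE)).sum())
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0

    def _ratio(num, den, name):
        if den == 0:
            logger.warning("%s denominator is 0; reporting 0", name)
            return 0.0
        return num / den

    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalMetrics(tp, fp, fn, tn, accuracy, recall, precision, f1)


def evaluate(model: ConvNet, x_test: np.ndarray, y_test: np.ndarray) -> EvalMetrics:
    """Confusion-count metrics of the model on a held-out set."""
    if len(x_test) == 0:
        raise ValidationError("test set must be non-empty")
    return metrics_from_predictions(y_test, model.predict(x_test))
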