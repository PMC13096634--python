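"""Candidate evaluation: composite objective, time proxy and metrics.

A candidate configuration theta is scored by the composite objective

    J(theta) = lambda1 * Loss(theta) + lambda2 * T(theta) / T_max

where ``Loss`` is the validation cross-entropy of a CNN trained with that
configuration and ``T`` a training-cost measure.  By default ``T`` is a
deterministic complexity proxy derived from the forward-pass cost of the
convolutional layers,

    T = epochs * n_batches * N * sum_i (L_i * F_i^2)

with ``N`` the batch size, ``L_i`` the filter count of conv layer ``i`` and
``F_i = 3`` the kernel side, normalized by the cost ``T_max`` of the most
expensive configuration in the search space.  Wall-clock measurement is
available via ``time_mode="measured"`` but is hardware-dependent and excluded
from every reproducibility check.

Metrics follow the usual multi-class conventions: accuracy is the confusion
trace over the total; precision, recall and F1 are computed one-vs-rest per
class (TP/(TP+FP), TP/(TP+FN), their harmonic mean) and macro-averaged.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .cnn import CNNClassifier
from .space import CNNConfig, HyperparameterSpace
from .synth import CLASS_NAMES, ImageDataset, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectiveWeights",
    "EvaluationResult",
    "cross_entropy",
    "time_proxy",
    "max_time_proxy",
    "confusion_from_predictions",
    "compute_metrics",
    "evaluate_candidate",
    "make_objective",
    "load_image_folder",
    "PENALTY_OBJECTIVE",
]

PENALTY_OBJECTIVE = 1e6


@dataclass(frozen=True)
class ObjectiveWeights:
    """Trade-off weights of the composite objective.

    ``lambda1`` scales the validation loss, ``lambda2`` the normalized
    training-cost term; ``time_normalizer`` is T_max.  ``time_mode`` selects
    the deterministic complexity proxy or wall-clock measurement.
    """

    lambda1: float = 1.0
    lambda2: float = 0.1
    time_normalizer: float = 1.0
    time_mode: str = "proxy"

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda1 + self.lambda2 <= 0:
            raise ValueError("weights must be nonnegative with a positive sum")
        if self.time_normalizer <= 0:
            raise ValueError("time_normalizer must be positive")
        if self.time_mode not in ("proxy", "measured"):
            raise ValueError("time_mode must be 'proxy' or 'measured'")


@dataclass
class EvaluationResult:
    """Per-candidate evaluation outcome."""

    config: CNNConfig
    loss: float
    time_measure: float
    objective: float
    metrics: dict = field(default_factory=dict)
    confusion: Optional[np.ndarray] = None


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-12) -> float:
    """Mean multi-class cross-entropy, -mean_n sum_i y_ni log(yhat_ni).

    ``y_true`` holds one-hot rows; ``y_pred`` probability rows (sums within
    1e-6 of one).  Probabilities are floored at ``eps`` before the log.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 2:
        raise ValueError("y_true and y_pred must be matching (n, C) arrays")
    if not np.allclose(y_pred.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each prediction row must sum to 1")
    return float(-(y_true * np.log(np.clip(y_pred, eps, None))).sum(axis=1).mean())


def time_proxy(config: CNNConfig, n_train: int, epochs: int, kernel_size: int = 3) -> float:
    """Deterministic training-cost surrogate from the conv forward-pass cost."""
    if n_train < 1 or epochs < 0:
        raise ValueError("n_train must be >= 1 and epochs >= 0")
    n_batches = math.ceil(n_train / config.batch_size)
    layer_cost = sum(filters * kernel_size**2
                     for filters in (config.base_filters, 2 * config.base_filters))
    return float(epochs * n_batches * config.batch_size * layer_cost)


def max_time_proxy(space: HyperparameterSpace, n_train: int, epochs: int) -> float:
    """Proxy cost of the most expensive configuration in the space (= T_max)."""
    lo, _hi = space.learning_rate_range
    costs = [
        time_proxy(CNNConfig(lo, b, f, space.dropout_choices[0], space.optimizer_choices[0]),
                   n_train, epochs)
        for b in space.batch_choices for f in space.filter_choices
    ]
    return max(costs)


def confusion_from_predictions(y_true, y_pred, n_classes: int = 4) -> np.ndarray:
    """Confusion counts, rows = true class, columns = predicted class."""
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def compute_metrics(confusion: np.ndarray) -> dict:
    """Accuracy plus macro-averaged precision, recall and F1 from a confusion
    matrix.  A class never predicted contributes precision 0 (logged); a class
    with no true members contributes recall 0.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion must be a non-empty square matrix")
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix holds no samples")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    accuracy = tp.sum() / total
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2.0 * precision * recall / (precision + recall), 0.0)
    for c in np.flatnonzero(tp + fp == 0):
        logger.info("class %d was never predicted; its precision counts as 0", c)
    return {
        "accuracy": float(accuracy),
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
        "per_class_precision": precision,
        "per_class_recall": recall,
        "per_class_f1": f1,
    }


def evaluate_candidate(
    config: CNNConfig,
    data: ImageDataset,
    weights: ObjectiveWeights,
    train_epochs: int = 3,
    seed: Optional[int] = None,
    val_fraction: float = 0.2,
    augmenter=None,
) -> EvaluationResult:
    """Train a CNN with ``config`` and score it with the composite objective.

    The training stack is split 80/20 into fit/validation folds, stratified by
    class and fixed by ``seed``; the loss term is the validation cross-entropy.
    In proxy time mode the whole evaluation is deterministic given the seed.
    A non-finite loss yields the large finite penalty objective instead of an
    exception.
    """
    if train_epochs < 1:
        raise ValueError("train_epochs must be >= 1")
    idx_fit, idx_val = train_test_split(
        np.arange(len(data)), test_size=val_fraction, stratify=data.labels,
        random_state=None if seed is None else int(seed) % (2**32),
    )
    clf = CNNClassifier(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        base_filters=config.base_filters,
        dropout=config.dropout_rate,
        optimizer=config.optimizer_kind,
        epochs=train_epochs,
        augmenter=augmenter,
        random_state=seed,
    )
    start = time.perf_counter()
    clf.fit(data.images[idx_fit], data.labels[idx_fit])
    elapsed = time.perf_counter() - start

    probs = clf.predict_proba(data.images[idx_val])
    onehot = np.eye(len(clf.classes_))[np.searchsorted(clf.classes_, data.labels[idx_val])]
    loss = cross_entropy(onehot, probs / probs.sum(axis=1, keepdims=True))

    if weights.time_mode == "measured":
        time_measure = elapsed
    else:
        time_measure = time_proxy(config, idx_fit.size, train_epochs)

    if not np.isfinite(loss):
        warnings.warn(f"non-finite loss for {config}; assigning penalty objective")
        objective = PENALTY_OBJECTIVE
        loss = float("inf")
    else:
        objective = weights.lambda1 * loss + weights.lambda2 * (time_measure / weights.time_normalizer)

    y_pred = clf.classes_[probs.argmax(axis=1)]
    cm = confusion_from_predictions(data.labels[idx_val], y_pred, n_classes=len(CLASS_NAMES))
    metrics = compute_metrics(cm)
    return EvaluationResult(config=config, loss=float(loss), time_measure=float(time_measure),
                            objective=float(objective), metrics=metrics, confusion=cm)


def make_objective(
    data: ImageDataset,
    weights: Optional[ObjectiveWeights] = None,
    train_epochs: int = 3,
    seed: Optional[int] = None,
    space: Optional[HyperparameterSpace] = None,
    augmenter=None,
    log: Optional[list] = None,
):
    """Build the ``CNNConfig -> J`` fitness function used by the optimizers.

    When ``weights`` is omitted, T_max defaults to the proxy cost of the most
    expensive configuration of ``space`` (so the time term lies in (0, 1]).
    ``log``, if given, collects one :class:`EvaluationResult` per evaluation.
    """
    space = space or HyperparameterSpace()
    if weights is None:
        n_fit = int(round(len(data) * 0.8))
        weights = ObjectiveWeights(time_normalizer=max_time_proxy(space, n_fit, train_epochs))

    def fitness(config: CNNConfig) -> float:
        result = evaluate_candidate(config, data, weights, train_epochs=train_epochs,
                                    seed=seed, augmenter=augmenter)
        if log is not None:
            log.append(result)
        return result.objective

    return fitness


def load_image_folder(path, image_size: int = 64, split_tag: str = "train") -> ImageDataset:
    """Read a class-subfolder layout of PNG/JPEG files into an ImageDataset.

    One subdirectory per class (e.g. glioma/meningioma/notumor/pituitary);
    images are converted to grayscale, resized to ``image_size`` squared with
    bilinear resampling and normalized by 255.
    """
    from PIL import Image

    root = Path(path)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories found under {root}")
    images, labels = [], []
    for c, cdir in enumerate(class_dirs):
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        for f in files:
            with Image.open(f) as im:
                arr = np.asarray(
                    im.convert("L").resize((image_size, image_size), Image.BILINEAR))
            images.append(normalize(arr))
            labels.append(c)
    if not images:
        raise ValueError(f"no image files found under {root}")
    return ImageDataset(
        images=np.asarray(images, dtype=np.float32),
        labels=np.asarray(labels, dtype=int),
        class_names=tuple(d.name for d in class_dirs),
        split_tag=split_tag,
    )
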