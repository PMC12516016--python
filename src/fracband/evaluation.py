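"""Dataset splitting and classification metrics.

The hold-out split uses fractions 0.72 / 0.08 / 0.20 with the rounding
convention: per class of size ``n``, train = floor(0.72 n), test =
round-half-up(0.20 n), validation = remainder.  Metrics are derived from
the confusion matrix (positive class = fracture); curve areas use the
trapezoidal rule (ROC) and step interpolation (PR).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc, average_precision_score, precision_recall_curve, roc_curve

__all__ = [
    "ClassificationMetrics",
    "ConfusionMatrix",
    "FoldSummary",
    "SplitSpec",
    "aggregate_folds",
    "compute_metrics",
    "f1_from_precision_recall",
    "kfold_indices",
    "roc_pr_curves",
    "stratified_split",
]


@dataclass
class SplitSpec:
    train: float = 0.72
    validation: float = 0.08
    test: float = 0.20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train + self.validation + self.test
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train, self.validation, self.test) < 0:
            raise ValueError("split fractions must be nonnegative")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(labels: np.ndarray, spec: SplitSpec | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-stratified (train, validation, test) index arrays.

    Within each class the indices are shuffled by the spec seed, then
    assigned train / test / validation according to the rounding
    convention above.  Partitions are disjoint and exhaustive.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    if spec.stratified and len(classes) < 2:
        raise ValueError("stratified split requires at least two classes")
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    groups = [labels == c for c in classes] if spec.stratified else [np.ones_like(labels, bool)]
    for mask in groups:
        idx = np.flatnonzero(mask)
        n = idx.size
        n_train = math.floor(spec.train * n)
        n_test = _round_half_up(spec.test * n)
        n_val = n - n_train - n_test
        for frac, count, name in ((spec.train, n_train, "train"),
                                  (spec.validation, n_val, "validation"),
                                  (spec.test, n_test, "test")):
            if frac > 0 and count <= 0:
                raise ValueError(
                    f"class of size {n} cannot populate the {name} partition "
                    "under the configured fractions"
                )
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:n_train + n_test])
        val_idx.append(perm[n_train + n_test:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(val_idx)),
            np.sort(np.concatenate(test_idx)))


def kfold_indices(labels: np.ndarray, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """``k`` stratified, disjoint, exhaustive folds; per-class fold sizes
    differ by at most one."""
    labels = np.asarray(labels).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    rng = np.random.default_rng(seed)
    folds: list[list[np.ndarray]] = [[] for _ in range(k)]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        for j, chunk in enumerate(np.array_split(idx, k)):
            folds[j].append(chunk)
    return [np.sort(np.concatenate(parts)) for parts in folds]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationMetrics:
    """Confusion-matrix scores as fractions in [0, 1] (kappa in [-1, 1]),
    plus curve areas when both classes are present."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    auroc: float
    auprc: float
    confusion: ConfusionMatrix
    warnings: list[str] = field(default_factory=list)

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "accuracy": self.accuracy * scale,
            "precision": self.precision * scale,
            "recall": self.recall * scale,
            "f1": self.f1 * scale,
            "kappa": self.kappa,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "fn": self.confusion.fn, "tn": self.confusion.tn},
            "warnings": list(self.warnings),
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); works on fractions or percentages alike."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _safe_ratio(num: float, den: float, name: str, warn: list[str]) -> float:
    if den == 0:
        warn.append(f"{name} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
                    ) -> ClassificationMetrics:
    """Threshold the scores (>= threshold is positive) and derive all
    confusion-matrix metrics plus AUROC / AUPRC."""
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_prob, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} labels vs {p.size} scores")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y_true must be binary (0/1)")
    pred = p >= threshold
    truth = y == 1.0
    cm = ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )
    warn: list[str] = []
    n = cm.total
    accuracy = (cm.tp + cm.tn) / n
    precision = _safe_ratio(cm.tp, cm.tp + cm.fp, "precision", warn)
    recall = _safe_ratio(cm.tp, cm.tp + cm.fn, "recall", warn)
    f1 = f1_from_precision_recall(precision, recall)
    # chance-corrected agreement with marginal-product expected agreement
    p_o = accuracy
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    kappa = _safe_ratio(p_o - p_e, 1.0 - p_e, "kappa", warn)
    if len(np.unique(y)) == 2:
        _, _, auroc, _, _, auprc = roc_pr_curves(y, p)
    else:
        warn.append("curve areas undefined for single-class truth; reported as 0")
        auroc = auprc = 0.0
    for message in warn:
        warnings.warn(message, stacklevel=2)
    return ClassificationMetrics(accuracy=accuracy, precision=precision, recall=recall,
                                 f1=f1, kappa=kappa, auroc=auroc, auprc=auprc,
                                 confusion=cm, warnings=warn)


def roc_pr_curves(y_true: np.ndarray, y_prob: np.ndarray):
    """ROC and PR curve points with their areas.

    Returns ``(fpr, tpr, auroc, precision, recall, auprc)``.  AUROC uses
    the trapezoidal rule over all thresholds; AUPRC uses step
    interpolation (average precision).
    """
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_prob, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute curves")
    fpr, tpr, _ = roc_curve(y, p)
    auroc = float(auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(y, p)
    auprc = float(average_precision_score(y, p))
    return fpr, tpr, auroc, precision, recall, auprc


@dataclass
class FoldSummary:
    """Per-fold metric values with their mean and population (divisor k)
    standard deviation."""

    metric_names: tuple[str, ...]
    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    std: dict[str, float]


def aggregate_folds(per_fold_metrics: list[dict[str, float]]) -> FoldSummary:
    """Aggregate cross-validation folds: arithmetic mean and population
    standard deviation per metric."""
    if len(per_fold_metrics) < 2:
        raise ValueError("at least two folds are required")
    names = tuple(per_fold_metrics[0])
    for fold in per_fold_metrics:
        if tuple(fold) != names:
            raise ValueError("folds report inconsistent metric names")
    mean, std = {}, {}
    for name in names:
        values = np.array([fold[name] for fold in per_fold_metrics], dtype=float)
        mean[name] = float(values.mean())
        std[name] = float(values.std(ddof=0))
    return FoldSummary(metric_names=names, per_fold=list(per_fold_metrics), mean=mean, std=std)
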