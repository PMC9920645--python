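"""Confusion matrices, micro/macro precision-recall, and split protocols.

Micro-averaged precision and recall are computed from class-summed counts:

    micro-P = sum_j TP_j / sum_j (TP_j + FP_j)
    micro-R = sum_j TP_j / sum_j (TP_j + FN_j)

For single-label classification both coincide with accuracy; macro averages
are emitted alongside so either convention can be inspected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "micro_metrics",
    "stratified_holdout",
    "kfold_stratified",
]


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """m x m count matrix, rows = true class, cols = predicted class (1..m)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true - 1, y_pred - 1), 1)
    return cm


def micro_metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """(micro_p, micro_r, accuracy); zero denominators yield 0 with a warning."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    tp = np.diag(cm).sum()
    total = cm.sum()
    fp = cm.sum(axis=0).sum() - tp
    fn = cm.sum(axis=1).sum() - tp

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"zero denominator for {name}; reporting 0", RuntimeWarning)
            return 0.0
        return float(num) / float(den)

    micro_p = _ratio(tp, tp + fp, "micro precision")
    micro_r = _ratio(tp, tp + fn, "micro recall")
    accuracy = _ratio(tp, total, "accuracy")
    return micro_p, micro_r, accuracy


def _macro_metrics(cm: np.ndarray) -> tuple[float, float]:
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
    return float(p.mean()), float(r.mean())


@dataclass
class EvalReport:
    confusion: np.ndarray
    accuracy: float
    micro_p: float
    micro_r: float
    macro_p: float
    macro_r: float
    per_class: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         n_classes: int | None = None) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=int)
        m = int(n_classes or max(y_true.max(), np.asarray(y_pred).max()))
        cm = confusion_matrix(y_true, y_pred, m)
        return cls.from_confusion(cm)

    @classmethod
    def from_confusion(cls, cm: np.ndarray) -> "EvalReport":
        cm = np.asarray(cm, dtype=int)
        micro_p, micro_r, accuracy = micro_metrics(cm)
        macro_p, macro_r = _macro_metrics(cm)
        tp = np.diag(cm)
        per_class = {
            "tp": tp.tolist(),
            "fp": (cm.sum(axis=0) - tp).tolist(),
            "fn": (cm.sum(axis=1) - tp).tolist(),
        }
        return cls(confusion=cm, accuracy=accuracy, micro_p=micro_p,
                   micro_r=micro_r, macro_p=macro_p, macro_r=macro_r,
                   per_class=per_class)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "micro_p": self.micro_p,
            "micro_r": self.micro_r,
            "macro_p": self.macro_p,
            "macro_r": self.macro_r,
            "per_class": self.per_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(confusion=np.asarray(d["confusion"], dtype=int),
                   accuracy=d["accuracy"], micro_p=d["micro_p"], micro_r=d["micro_r"],
                   macro_p=d["macro_p"], macro_r=d["macro_r"],
                   per_class=d.get("per_class", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def confusion_csv(self, path: str | Path) -> None:
        m = self.confusion.shape[0]
        labels = [str(i + 1) for i in range(m)]
        pd.DataFrame(self.confusion, index=labels, columns=labels).to_csv(path)


def stratified_holdout(y: np.ndarray, frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random holdout: round(frac * count) indices go to test.

    Deterministic for a given seed; train and test are disjoint and together
    cover every index.
    """
    y = np.asarray(y, dtype=int)
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_test = int(np.floor(frac * idx.size + 0.5))
        if n_test < 1 or n_test >= idx.size:
            raise ValueError(f"class {c} too small for holdout frac {frac}")
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def kfold_stratified(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold id (0..folds-1) per index: per-class shuffle then round-robin.

    Per-class fold sizes differ by at most one.
    """
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y)[np.unique(y)]
    if folds > counts.min():
        raise ValueError("folds exceeds the smallest class count")
    rng = np.random.default_rng(seed)
    assign = np.empty(y.shape[0], dtype=int)
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        assign[idx] = np.arange(idx.size) % folds
    return assign
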