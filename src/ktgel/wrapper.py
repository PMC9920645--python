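"""Wrapper feature selection: swarm search over feature masks, scored by an ELM.

The fitness of a candidate bit mask is the mean stratified k-fold validation
accuracy of an ELM retrained on the masked feature columns.  Fold assignment
is fixed per run, so fitness is a deterministic function of the mask given
the seed.  Final ties are broken toward fewer selected features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elm import ELMConfig, LabeledFeatureSet, hidden_output, init_random_layer, one_hot, solve_beta
from .evaluation import kfold_stratified
from .swarm import GOAParams, SwarmResult, optimize

__all__ = ["FeatureMask", "wrapper_fitness", "select_features", "cv_accuracy"]


@dataclass
class FeatureMask:
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("feature mask must be a 1-D bit vector")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def __str__(self) -> str:
        return "".join("1" if v else "0" for v in self.bits)


def _cv_accuracy(X: np.ndarray, y: np.ndarray, n_classes: int, W: np.ndarray,
                 b: np.ndarray, activation: str, fold_assign: np.ndarray) -> float:
    """Mean validation accuracy over folds for a fixed hidden layer (W, b)."""
    H = hidden_output(X, W, b, activation)
    T = one_hot(y, n_classes)
    accs = []
    for f in np.unique(fold_assign):
        val = fold_assign == f
        beta = solve_beta(H[~val], T[~val])
        pred = np.argmax(H[val] @ beta, axis=1) + 1
        accs.append(float(np.mean(pred == y[val])))
    return float(np.mean(accs))


def cv_accuracy(data: LabeledFeatureSet, elm_cfg: ELMConfig, folds: int) -> float:
    """Plain ELM cross-validation accuracy on the full feature set."""
    W, b = init_random_layer(data.n_features, elm_cfg.n_hidden, elm_cfg.seed)
    fold_assign = kfold_stratified(data.y, folds, elm_cfg.seed)
    return _cv_accuracy(data.X, data.y, data.n_classes, W, b,
                        elm_cfg.activation, fold_assign)


def wrapper_fitness(mask, data: LabeledFeatureSet, elm_cfg: ELMConfig,
                    folds: int) -> float:
    """CV accuracy of an ELM on the masked columns; the all-zero mask scores 0."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask, dtype=np.uint8)
    if bits.shape[0] != data.n_features:
        raise ValueError("mask length must equal the number of features")
    sel = np.flatnonzero(bits)
    if sel.size == 0:
        return 0.0
    W, b = init_random_layer(sel.size, elm_cfg.n_hidden, elm_cfg.seed)
    fold_assign = kfold_stratified(data.y, folds, elm_cfg.seed)
    return _cv_accuracy(data.X[:, sel], data.y, data.n_classes, W, b,
                        elm_cfg.activation, fold_assign)


def select_features(data: LabeledFeatureSet, goa: GOAParams, elm_cfg: ELMConfig,
                    folds: int = 5, variant: str = "ktgoa") -> tuple[FeatureMask, SwarmResult]:
    """Swarm search over feature masks; ties broken toward fewer features."""
    n = data.n_features
    if n == 1:
        ones = FeatureMask(np.ones(1, dtype=np.uint8))
        return ones, SwarmResult(best_position=ones.bits, best_fitness=float("nan"),
                                 history=np.asarray([]))
    tracker = {"bits": None, "fitness": -np.inf, "count": n + 1}

    def fitness(bits: np.ndarray) -> float:
        acc = wrapper_fitness(bits, data, elm_cfg, folds)
        cnt = int(bits.sum())
        if acc > tracker["fitness"] or (acc == tracker["fitness"] and cnt < tracker["count"]):
            tracker.update(bits=bits.copy(), fitness=acc, count=cnt)
        return acc

    result = optimize(fitness, n, goa, variant=variant)
    return FeatureMask(tracker["bits"]), result
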