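"""Weight-level ELM pruning by binary swarm search over an input-weight mask.

A binary mask of shape ``n_features x n_hidden`` sits on top of a single,
fixed random hidden layer.  Masked-out weights are exactly zero, so a hidden
node with an all-zero column is dead (its bias goes with it) and a feature
with an all-zero row is eliminated: one weight couples to one feature, but a
feature couples to many weights, so a feature only disappears when all of its
weights do.  The mask is searched with the k-tournament swarm optimizer,
using stratified cross-validation accuracy as fitness; the final model is
compacted to the surviving nodes and its output weights refit on the full
training split.

At realistic scale the search space is huge (n * L bits, e.g. 48 x 3000 =
144,000); runs at that scale need patience, and the test suite sticks to
small hidden layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .elm import (ELMConfig, ELMModel, LabeledFeatureSet, hidden_output,
                  init_random_layer, one_hot, predict, solve_beta)
from .evaluation import kfold_stratified
from .swarm import GOAParams, SwarmResult, optimize
from .wrapper import _cv_accuracy

__all__ = [
    "WeightMask",
    "PrunedELMModel",
    "apply_weight_mask",
    "derive_pruning",
    "masked_fitness",
    "model_from_mask",
    "train_ktgel",
    "predict_pruned",
    "save_pruned",
    "load_pruned",
]


@dataclass
class WeightMask:
    """Binary matrix over the input weights; 1 = weight kept."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError("weight mask must be a 2-D bit matrix")

    @property
    def n_features(self) -> int:
        return self.bits.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.bits.shape[1]

    @property
    def n_kept(self) -> int:
        return int(self.bits.sum())

    def active_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.bits.any(axis=0))

    def active_features(self) -> np.ndarray:
        return np.flatnonzero(self.bits.any(axis=1))


@dataclass
class PrunedELMModel:
    """Compacted masked ELM: only surviving hidden nodes are materialized.

    ``base.W`` keeps the full feature width (rows of eliminated features are
    all zero), so prediction consumes full-width inputs and is bit-identical
    to predicting with the non-compacted masked model.
    """

    base: ELMModel
    active_nodes: np.ndarray
    active_features: np.ndarray
    mask: WeightMask
    fitness: float

    @property
    def n_active_nodes(self) -> int:
        return int(self.active_nodes.size)


def apply_weight_mask(W: np.ndarray, mask: WeightMask | np.ndarray) -> np.ndarray:
    bits = mask.bits if isinstance(mask, WeightMask) else np.asarray(mask, dtype=np.uint8)
    W = np.asarray(W, dtype=float)
    if W.shape != bits.shape:
        raise ValueError(f"mask shape {bits.shape} must match W shape {W.shape}")
    return W * bits


def derive_pruning(mask: WeightMask | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(active node indices, active feature indices), both 0-based."""
    m = mask if isinstance(mask, WeightMask) else WeightMask(mask)
    return m.active_nodes(), m.active_features()


def masked_fitness(mask, data: LabeledFeatureSet, W: np.ndarray, b: np.ndarray,
                   elm_cfg: ELMConfig, folds: int) -> float:
    """CV accuracy of the masked ELM; the all-zero mask scores 0.

    Dead nodes' columns (and biases) are excluded before computing H, so the
    fitness depends only on retained weights.
    """
    bits = mask.bits if isinstance(mask, WeightMask) else np.asarray(mask, dtype=np.uint8)
    if bits.shape != W.shape:
        raise ValueError("mask shape must match W shape")
    if not bits.any():
        return 0.0
    Wm = W * bits
    act = np.flatnonzero(bits.any(axis=0))
    fold_assign = kfold_stratified(data.y, folds, elm_cfg.seed)
    return _cv_accuracy(data.X, data.y, data.n_classes, Wm[:, act], b[act],
                        elm_cfg.activation, fold_assign)


def model_from_mask(data: LabeledFeatureSet, W: np.ndarray, b: np.ndarray,
                    mask: WeightMask, elm_cfg: ELMConfig,
                    fitness: float = float("nan")) -> PrunedELMModel:
    """Compact the masked layer and refit beta on the full training split."""
    act_nodes, act_feats = derive_pruning(mask)
    if act_nodes.size == 0:
        raise ValueError("mask leaves no active hidden node")
    Wc = (W * mask.bits)[:, act_nodes]
    bc = b[act_nodes]
    H = hidden_output(data.X, Wc, bc, elm_cfg.activation)
    beta = solve_beta(H, one_hot(data.y, data.n_classes))
    base = ELMModel(W=Wc, b=bc, beta=beta, activation=elm_cfg.activation,
                    seed=elm_cfg.seed, class_names=data.class_names)
    return PrunedELMModel(base=base, active_nodes=act_nodes,
                          active_features=act_feats, mask=mask, fitness=fitness)


def train_ktgel(data: LabeledFeatureSet, n_hidden: int, goa: GOAParams,
                elm_cfg: ELMConfig | None = None, folds: int = 3,
                variant: str = "ktgoa",
                node_penalty: float = 0.0) -> tuple[PrunedELMModel, SwarmResult]:
    """Search a weight mask over a fixed random layer; return the pruned model.

    The hidden layer is generated once from ``elm_cfg.seed``; the swarm then
    maximizes ``masked_fitness`` over ``n_features * n_hidden`` bits.  The
    all-ones agent seeds the initial population, so the returned model is
    never worse (in search fitness) than the unpruned ELM.  ``node_penalty``
    optionally subtracts ``penalty * kept_fraction`` from the fitness
    (default 0: pure validation accuracy).
    """
    if elm_cfg is None:
        elm_cfg = ELMConfig(n_hidden=n_hidden, seed=goa.seed)
    n = data.n_features
    W, b = init_random_layer(n, n_hidden, elm_cfg.seed)
    D = n * n_hidden

    def fitness(bits: np.ndarray) -> float:
        val = masked_fitness(bits.reshape(n, n_hidden), data, W, b, elm_cfg, folds)
        if node_penalty:
            val -= node_penalty * bits.sum() / D
        return val

    result = optimize(fitness, D, goa, variant=variant)
    mask = WeightMask(result.best_position.reshape(n, n_hidden))
    model = model_from_mask(data, W, b, mask, elm_cfg, fitness=result.best_fitness)
    return model, result


def predict_pruned(model: PrunedELMModel, X: np.ndarray) -> np.ndarray:
    """Labels on full-width inputs; identical to predicting the masked model."""
    return predict(model.base, X)


def _rle_encode(bits: np.ndarray) -> list[int]:
    """Run lengths of a flat bit vector, starting with the length of the
    initial run of zeros (possibly 0)."""
    flat = np.asarray(bits, dtype=np.uint8).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], change, [flat.size]))).tolist()
    if flat[0] == 1:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], size: int) -> np.ndarray:
    out = np.empty(size, dtype=np.uint8)
    pos, val = 0, 0
    for r in runs:
        out[pos:pos + r] = val
        pos += r
        val ^= 1
    if pos != size:
        raise ValueError("run-length data does not match the expected size")
    return out


def save_pruned(model: PrunedELMModel, path: str | Path) -> None:
    d = model.base.to_dict()
    d.update({
        "mask_shape": list(model.mask.bits.shape),
        "mask_rle": _rle_encode(model.mask.bits),
        "active_nodes": model.active_nodes.tolist(),
        "active_features": model.active_features.tolist(),
        "fitness": model.fitness,
    })
    Path(path).write_text(json.dumps(d) + "\n")


def load_pruned(path: str | Path) -> PrunedELMModel:
    d = json.loads(Path(path).read_text())
    shape = tuple(d["mask_shape"])
    mask = WeightMask(_rle_decode(d["mask_rle"], shape[0] * shape[1]).reshape(shape))
    return PrunedELMModel(
        base=ELMModel.from_dict(d),
        active_nodes=np.asarray(d["active_nodes"], dtype=int),
        active_features=np.asarray(d["active_features"], dtype=int),
        mask=mask,
        fitness=float(d.get("fitness", float("nan"))),
    )
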