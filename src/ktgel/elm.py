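"""Extreme learning machine: random hidden layer, least-squares output weights.

The ELM is a single-hidden-layer feed-forward network whose input weights
``W`` and biases ``b`` are drawn at random and never trained.  Only the
output weights ``beta`` are fitted, by solving the linear system
``H @ beta = T`` in the least-squares / minimum-norm sense via the
Moore-Penrose pseudoinverse of the hidden-layer output matrix ``H``.

Class labels are integers ``1..m``; targets are one-hot rows in {0, 1} and
predictions decode by argmax with ties broken toward the lowest class index.
Features are assumed pre-normalized (see :mod:`ktgel.features`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ACTIVATIONS",
    "LabeledFeatureSet",
    "ELMModel",
    "ELMConfig",
    "init_random_layer",
    "hidden_output",
    "one_hot",
    "train_elm",
    "predict",
    "decision_scores",
    "save_model",
    "load_model",
    "load_feature_csv",
    "save_feature_csv",
]

# Singular values below PINV_RTOL * sigma_max are treated as zero.
PINV_RTOL = 1e-10

ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "rbf": lambda z: np.exp(-np.square(z)),
}


@dataclass
class LabeledFeatureSet:
    """Observations-by-features matrix with integer class labels in ``1..m``."""

    X: np.ndarray
    y: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing entries")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must equal the number of rows of X")
        if self.y.size == 0:
            raise ValueError("empty dataset")
        m = int(self.y.max())
        if self.y.min() < 1:
            raise ValueError("labels must lie in 1..m")
        counts = np.bincount(self.y, minlength=m + 1)[1:]
        if (counts == 0).any():
            raise ValueError("every class in 1..m must have at least one observation")
        if m < 2:
            raise ValueError("at least two classes are required")
        if self.class_names is not None and len(self.class_names) != m:
            raise ValueError("class_names length must equal the number of classes")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max())

    def subset(self, idx: np.ndarray) -> "LabeledFeatureSet":
        """Row subset; the subset must still contain every class."""
        return LabeledFeatureSet(self.X[idx], self.y[idx], self.class_names)


@dataclass
class ELMConfig:
    """Hyper-parameters shared by every ELM fit inside a search."""

    n_hidden: int
    seed: int = 0
    activation: str = "sigmoid"


@dataclass
class ELMModel:
    W: np.ndarray          # n_features x n_hidden input weights
    b: np.ndarray          # n_hidden biases
    beta: np.ndarray       # n_hidden x n_classes output weights
    activation: str = "sigmoid"
    seed: int = 0
    class_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.W.shape[1] != self.b.shape[0] or self.beta.shape[0] != self.b.shape[0]:
            raise ValueError("inconsistent shapes: cols(W) = len(b) = rows(beta) required")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @property
    def n_classes(self) -> int:
        return self.beta.shape[1]

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_hidden": self.n_hidden,
            "n_classes": self.n_classes,
            "activation": self.activation,
            "seed": self.seed,
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "beta": self.beta.tolist(),
            "class_names": self.class_names,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ELMModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            activation=d.get("activation", "sigmoid"),
            seed=int(d.get("seed", 0)),
            class_names=d.get("class_names"),
        )


def init_random_layer(n_features: int, n_hidden: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw input weights and biases i.i.d. uniform on [-1, 1], reproducibly."""
    if n_features < 1 or n_hidden < 1:
        raise ValueError("n_features and n_hidden must be positive")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_features, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    return W, b


def hidden_output(X: np.ndarray, W: np.ndarray, b: np.ndarray,
                  activation: str = "sigmoid") -> np.ndarray:
    """Hidden layer output matrix H[i, j] = g(x_i . w_j + b_j)."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if X.ndim != 2 or W.ndim != 2 or X.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs W {W.shape}")
    if W.shape[1] != b.shape[0]:
        raise ValueError("bias length must equal the number of hidden nodes")
    try:
        g = ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None
    return g(X @ W + b)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    """{0,1} one-hot target matrix, N x m, for labels in 1..m."""
    y = np.asarray(y, dtype=int)
    T = np.zeros((y.shape[0], n_classes))
    T[np.arange(y.shape[0]), y - 1] = 1.0
    return T


def solve_beta(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = pinv(H) @ T."""
    return np.linalg.pinv(H, rcond=PINV_RTOL) @ T


def train_elm(data: LabeledFeatureSet, n_hidden: int, seed: int = 0,
              activation: str = "sigmoid") -> ELMModel:
    W, b = init_random_layer(data.n_features, n_hidden, seed)
    H = hidden_output(data.X, W, b, activation)
    T = one_hot(data.y, data.n_classes)
    beta = solve_beta(H, T)
    return ELMModel(W=W, b=b, beta=beta, activation=activation, seed=seed,
                    class_names=data.class_names)


def decision_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} feature columns, got {X.shape}")
    H = hidden_output(X, model.W, model.b, model.activation)
    return H @ model.beta


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Labels 1..m by argmax score; ties break toward the lowest class index."""
    return np.argmax(decision_scores(model, X), axis=1) + 1


def save_model(model: ELMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()) + "\n")


def load_model(path: str | Path) -> ELMModel:
    return ELMModel.from_dict(json.loads(Path(path).read_text()))


def load_feature_csv(path: str | Path) -> LabeledFeatureSet:
    """Read a feature matrix CSV with a header and a ``label`` column."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must contain a 'label' column")
    y = df["label"].to_numpy()
    X = df.drop(columns=["label"]).to_numpy(dtype=float)
    if not np.issubdtype(np.asarray(y).dtype, np.integer):
        raise ValueError("labels must be integers in 1..m")
    return LabeledFeatureSet(X, y)


def save_feature_csv(data: LabeledFeatureSet, path: str | Path,
                     feature_names: list[str] | None = None) -> None:
    names = feature_names or [f"f{i + 1}" for i in range(data.n_features)]
    df = pd.DataFrame(data.X, columns=names)
    df["label"] = data.y
    df.to_csv(path, index=False)
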