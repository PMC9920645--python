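"""Window-level statistics for multi-channel FMG signals, plus min-max scaling.

Each signal window yields six statistics per channel, concatenated in channel
order: min, max, RMS, variance, standard deviation, mean.  Variance and
standard deviation use the sample (N-1) convention.  Min-max normalization
parameters are fitted on training rows only and applied unclamped elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .elm import LabeledFeatureSet

__all__ = [
    "SignalWindow",
    "STAT_NAMES",
    "extract_features",
    "feature_names",
    "minmax_fit",
    "minmax_apply",
    "windows_to_dataset",
    "read_signal_csv",
    "write_signal_csv",
]

STAT_NAMES = ("min", "max", "rms", "var", "std", "mean")


@dataclass
class SignalWindow:
    """T x C block of samples (volts) for one gesture repetition."""

    samples: np.ndarray
    rate: float
    label: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a T x C matrix")
        if self.samples.shape[0] < 2 or self.samples.shape[1] < 1:
            raise ValueError("need T >= 2 samples and C >= 1 channels")
        if np.isnan(self.samples).any():
            raise ValueError("missing samples in window")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def extract_features(window: SignalWindow) -> np.ndarray:
    """Length 6*C vector: per channel (min, max, rms, var, std, mean)."""
    s = window.samples
    if s.shape[0] < 2:
        raise ValueError("variance requires at least two samples")
    stats = np.stack([
        s.min(axis=0),
        s.max(axis=0),
        np.sqrt(np.mean(np.square(s), axis=0)),
        s.var(axis=0, ddof=1),
        s.std(axis=0, ddof=1),
        s.mean(axis=0),
    ])  # 6 x C
    return stats.T.ravel()


def feature_names(n_channels: int) -> list[str]:
    return [f"ch{c + 1}_{stat}" for c in range(n_channels) for stat in STAT_NAMES]


def minmax_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("cannot fit min-max scaling on an empty matrix")
    return X.min(axis=0), X.max(axis=0)


def minmax_apply(X: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    """x' = (x - min) / (max - min); constant columns map to 0; no clamping."""
    X = np.asarray(X, dtype=float)
    span = np.asarray(maxs, dtype=float) - np.asarray(mins, dtype=float)
    safe = np.where(span == 0, 1.0, span)
    out = (X - mins) / safe
    out[:, span == 0] = 0.0
    return out


def windows_to_dataset(windows: list[SignalWindow],
                       class_names: list[str] | None = None) -> LabeledFeatureSet:
    X = np.stack([extract_features(w) for w in windows])
    y = np.asarray([w.label for w in windows], dtype=int)
    return LabeledFeatureSet(X, y, class_names)


def read_signal_csv(raw_path: str | Path, manifest_path: str | Path) -> list[SignalWindow]:
    """Load windows from a raw signal CSV plus a trial manifest.

    The raw CSV has columns ``t, ch1..chC``.  The manifest has columns
    ``trial_id, start_row, end_row, label`` where ``start_row`` is a 0-based
    inclusive index into the raw rows and ``end_row`` is exclusive.
    """
    raw = pd.read_csv(raw_path)
    channels = [c for c in raw.columns if c.startswith("ch")]
    if not channels:
        raise ValueError("raw CSV must contain ch1..chC columns")
    samples = raw[channels].to_numpy(dtype=float)
    t = raw["t"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(t[: min(len(t), 1000)])) if len(t) > 1 else 0.0
    manifest = pd.read_csv(manifest_path)
    windows = []
    for row in manifest.itertuples():
        block = samples[int(row.start_row):int(row.end_row)]
        windows.append(SignalWindow(block, rate=rate, label=int(row.label)))
    return windows


def write_signal_csv(windows: list[SignalWindow], raw_path: str | Path,
                     manifest_path: str | Path,
                     extra_cols: dict[str, list] | None = None) -> None:
    """Stack windows into a raw CSV and emit the matching trial manifest."""
    if not windows:
        raise ValueError("no windows to write")
    rate = windows[0].rate
    blocks, rows = [], []
    start = 0
    for i, w in enumerate(windows):
        T = w.samples.shape[0]
        blocks.append(w.samples)
        rows.append({"trial_id": i, "start_row": start, "end_row": start + T,
                     "label": w.label})
        start += T
    stacked = np.vstack(blocks)
    df = pd.DataFrame(stacked, columns=[f"ch{c + 1}" for c in range(stacked.shape[1])])
    df.insert(0, "t", np.arange(stacked.shape[0]) / rate)
    df.to_csv(raw_path, index=False)
    mdf = pd.DataFrame(rows)
    for name, vals in (extra_cols or {}).items():
        mdf[name] = vals
    mdf.to_csv(manifest_path, index=False)
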