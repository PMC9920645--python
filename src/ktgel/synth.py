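"""Seeded generator of FMG-like multi-channel gesture windows.

Each gesture class has a per-channel mean-activation template (volts, inside
the 0-3.3 V voltage-divider range).  Subjects perturb the templates
additively; within a window the samples follow an order-1 autoregressive
process around the subject-level mean.  A single ``ambiguity`` knob pulls
the templates of designated confusable groups toward their group centroid
(1.0 collapses them onto each other), which controls between-class overlap
without touching unrelated classes.

Three presets mirror gesture sets of increasing ambiguity: ``low`` (nine
digits, one confusable group), ``middle`` (ten letters, two groups, one
amplitude-boosted dynamic sign) and ``high`` (twenty signs with five
confusable pairs and a boosted dynamic sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .features import SignalWindow

__all__ = ["GestureTemplate", "GenConfig", "PRESETS", "preset_config",
           "make_templates", "generate"]

V_MAX = 3.3           # voltage-divider ceiling
_TEMPLATE_LO, _TEMPLATE_HI = 0.3, 3.0


@dataclass
class GestureTemplate:
    class_id: int
    mu: np.ndarray
    confusable_with: list[int] = field(default_factory=list)


@dataclass
class GenConfig:
    n_classes: int
    n_channels: int = 8
    n_subjects: int = 10
    reps_per_subject: int = 10
    rate: float = 100.0
    window_seconds: float = 1.0
    subject_sd: float = 0.2
    noise_sd: float = 0.1
    ar_coeff: float = 0.3
    ambiguity: float = 0.0
    d_min: float = 1.0
    confusable_groups: list[list[int]] = field(default_factory=list)
    boosted_classes: dict[int, float] = field(default_factory=dict)
    informative_channels: list[int] | None = None
    class_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two gesture classes")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if not (0.0 <= self.ambiguity <= 1.0):
            raise ValueError("ambiguity must lie in [0, 1]")
        for group in self.confusable_groups:
            for cid in group:
                if not (1 <= cid <= self.n_classes):
                    raise ValueError(f"confusable class id {cid} out of range")


# Class-name rosters for the presets.  In the high set the five confusable
# pairs are (B,4), (M,N), (U,2), (6,W), (S,T); J and Z are dynamic signs
# emulated as amplitude-boosted static templates.
_HIGH_NAMES = ["B", "4", "M", "N", "U", "2", "6", "W", "S", "T",
               "A", "C", "E", "F", "G", "H", "K", "L", "O", "Z"]

# Difficulty knobs (subject_sd, d_min, ambiguity) are tuned so that, at ten
# subjects, the eight-channel band classifies well while channel truncation
# and rising ambiguity measurably degrade accuracy.
PRESETS: dict[str, dict] = {
    "low": dict(
        n_classes=9,
        class_names=[str(i) for i in range(1, 10)],
        confusable_groups=[[6, 7, 8, 9]],
        ambiguity=0.65,
        subject_sd=0.6,
        d_min=0.8,
    ),
    "middle": dict(
        n_classes=10,
        class_names=list("ABCDEFGHIJ"),
        confusable_groups=[[1, 3, 5], [7, 8]],   # A/C/E and G/H
        ambiguity=0.55,
        subject_sd=0.6,
        d_min=0.8,
        boosted_classes={10: 1.3},               # J: dynamic, stronger signal
    ),
    "high": dict(
        n_classes=20,
        class_names=_HIGH_NAMES,
        confusable_groups=[[1, 2], [3, 4], [5, 6], [7, 8], [9, 10]],
        ambiguity=0.8,
        subject_sd=0.6,
        d_min=0.8,
        boosted_classes={20: 1.3},               # Z: dynamic, stronger signal
    ),
}


def preset_config(name: str, **overrides) -> GenConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return GenConfig(**kwargs)


def make_templates(cfg: GenConfig) -> list[GestureTemplate]:
    """Draw per-class templates at mutual distance >= d_min, then apply the
    ambiguity shrink within confusable groups and any amplitude boosts."""
    rng = np.random.default_rng(cfg.seed)
    C = cfg.n_channels
    inf = (np.asarray(cfg.informative_channels, dtype=int) - 1
           if cfg.informative_channels is not None else np.arange(C))
    mus: list[np.ndarray] = []
    tries = 0
    while len(mus) < cfg.n_classes:
        cand = np.full(C, (_TEMPLATE_LO + _TEMPLATE_HI) / 2.0)
        cand[inf] = rng.uniform(_TEMPLATE_LO, _TEMPLATE_HI, size=inf.size)
        if all(np.linalg.norm(cand - m) >= cfg.d_min for m in mus):
            mus.append(cand)
        tries += 1
        if tries > 20000:
            raise ValueError("cannot place templates at the requested spacing; "
                             "reduce n_classes or d_min, or add channels")
    confusable = {i + 1: [] for i in range(cfg.n_classes)}
    for group in cfg.confusable_groups:
        centroid = np.mean([mus[c - 1] for c in group], axis=0)
        for c in group:
            mus[c - 1] = mus[c - 1] + cfg.ambiguity * (centroid - mus[c - 1])
            confusable[c] = [g for g in group if g != c]
    for cid, factor in cfg.boosted_classes.items():
        mus[cid - 1] = np.clip(mus[cid - 1] * factor, 0.0, V_MAX)
    return [GestureTemplate(i + 1, mus[i], confusable[i + 1])
            for i in range(cfg.n_classes)]


def _ar1_noise(rng: np.random.Generator, T: int, C: int, sd: float,
               phi: float) -> np.ndarray:
    """Stationary AR(1) noise, innovation sd ``sd``: e_t = phi e_{t-1} + eps_t."""
    e0 = rng.normal(0.0, sd / np.sqrt(1.0 - phi ** 2) if phi else sd, size=C)
    innov = rng.normal(0.0, sd, size=(T, C)) if sd else np.zeros((T, C))
    if phi == 0.0:
        return innov
    out, _ = lfilter([1.0], [1.0, -phi], innov, axis=0, zi=(phi * e0)[None, :])
    return out


def generate(cfg: GenConfig) -> tuple[list[SignalWindow], pd.DataFrame]:
    """Balanced windows: n_subjects * reps_per_subject per class.

    Templates derive from ``cfg.seed``; subject jitter and window noise from
    ``cfg.seed + 1``.  Subject jitter is drawn per (class, subject) and, when
    ``informative_channels`` is set, restricted to those channels so the
    remaining channels are pure noise carrying no class information.
    """
    templates = make_templates(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    T = int(round(cfg.rate * cfg.window_seconds))
    C = cfg.n_channels
    jitter_mask = np.zeros(C)
    inf = (np.asarray(cfg.informative_channels, dtype=int) - 1
           if cfg.informative_channels is not None else np.arange(C))
    jitter_mask[inf] = 1.0

    windows: list[SignalWindow] = []
    rows = []
    names = cfg.class_names
    for tpl in templates:
        for s in range(cfg.n_subjects):
            subj_mu = tpl.mu + jitter_mask * rng.normal(0.0, cfg.subject_sd, size=C)
            for _ in range(cfg.reps_per_subject):
                noise = _ar1_noise(rng, T, C, cfg.noise_sd, cfg.ar_coeff)
                samples = np.clip(subj_mu + noise, 0.0, V_MAX)
                windows.append(SignalWindow(samples, rate=cfg.rate, label=tpl.class_id))
                rows.append({
                    "trial_id": len(rows),
                    "label": tpl.class_id,
                    "class_name": names[tpl.class_id - 1] if names else str(tpl.class_id),
                    "subject": s + 1,
                })
    manifest = pd.DataFrame(rows)
    start = np.arange(len(windows)) * T
    manifest["start_row"] = start
    manifest["end_row"] = start + T
    return windows, manifest


def variant(cfg: GenConfig, **overrides) -> GenConfig:
    """Copy of a config with fields replaced (e.g. a 6-channel variant)."""
    return replace(cfg, **overrides)
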