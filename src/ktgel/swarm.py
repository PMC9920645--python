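"""Binary grasshopper swarm optimizer with optional k-tournament attraction.

Generic maximizer over fixed-length bit vectors.  Agents move under pairwise
social forces plus attraction to a best solution; the continuous displacement
is mapped back to bits through an S-shaped (logistic) transfer function.
Two variants share one loop:

* ``"bgoa"``  — every agent is attracted to the best agent of the current
  population;
* ``"ktgoa"`` — each agent is attracted to the winner of an independent
  k-tournament over the current population.

Both variants consume identical random draws, so with ``k == pop_size`` they
produce bit-identical trajectories for equal seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "GOAParams",
    "SwarmResult",
    "social_force",
    "coefficient_schedule",
    "tournament_select",
    "goa_displacement",
    "binarize",
    "optimize",
]

# Search box for the binary problem: bits live on [0, 1].
_UB, _LB = 1.0, 0.0
# Pairwise distances are rescaled into this interval before applying the
# social force, so that its non-trivial region is actually exercised.
_DIST_LO, _DIST_HI = 1.0, 4.0


@dataclass
class GOAParams:
    pop_size: int
    max_iter: int
    c_max: float = 1.0
    c_min: float = 0.00004
    f_intensity: float = 0.5
    l_scale: float = 1.5
    k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (self.c_max > self.c_min > 0):
            raise ValueError("require c_max > c_min > 0")
        if not (1 <= self.k <= self.pop_size):
            raise ValueError("require 1 <= k <= pop_size")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray           # elitist best fitness, length max_iter + 1
    trace: list[dict] = field(default_factory=list)
    n_evaluations: int = 0

    def __iter__(self):
        return iter((self.best_position, self.best_fitness, self.history))


def social_force(r, f_intensity: float = 0.5, l_scale: float = 1.5):
    """s(r) = f * exp(-r / l) - exp(-r): repulsive near 0, attractive beyond."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    out = f_intensity * np.exp(-r / l_scale) - np.exp(-r)
    return float(out) if out.ndim == 0 else out


def coefficient_schedule(iteration: int, params: GOAParams) -> float:
    """Linearly decaying exploration-exploitation coefficient, 1-based iteration."""
    if not (1 <= iteration <= params.max_iter):
        raise ValueError(f"iteration {iteration} outside 1..{params.max_iter}")
    return params.c_max - iteration * (params.c_max - params.c_min) / params.max_iter


def tournament_select(fitnesses: np.ndarray, k: int, rng: np.random.Generator) -> int:
    """Index of the fittest of k distinct uniform draws; ties -> lowest index."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    n = fitnesses.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in 1..{n}")
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return int(idx[np.argmax(fitnesses[idx])])


def _scaled_distances(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw pairwise Euclidean distances and their rescale into [1, 4].

    Rescaling is linear over the distinct nonzero range per call; degenerate
    populations (all pairwise distances equal) skip rescaling.  Zero-distance
    pairs are left at zero; they contribute no force.
    """
    pos = positions.astype(float)
    sq = np.sum(pos ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * pos @ pos.T, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    nz = d[d > 0]
    scaled = d.copy()
    if nz.size:
        lo, hi = nz.min(), nz.max()
        if hi > lo:
            scaled[d > 0] = _DIST_LO + (_DIST_HI - _DIST_LO) * (d[d > 0] - lo) / (hi - lo)
    return d, scaled


def goa_displacement(positions: np.ndarray, agent: int, attractor: np.ndarray,
                     c: float, f_intensity: float = 0.5, l_scale: float = 1.5,
                     distances: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Continuous update for one agent: social sum plus the attractor.

    v = c * sum_{j != i} [ c (ub-lb)/2 * s(d'_ij) * (x_j - x_i) / d_ij ] + attractor

    with d_ij the raw Euclidean distance and d'_ij its [1, 4] rescale.
    Coincident pairs (d_ij = 0) contribute zero.
    """
    positions = np.asarray(positions)
    attractor = np.asarray(attractor, dtype=float)
    if attractor.shape[0] != positions.shape[1]:
        raise ValueError("attractor length must equal the bit-vector length")
    d_raw, d_scaled = distances if distances is not None else _scaled_distances(positions)
    diff = positions.astype(float) - positions[agent].astype(float)   # (P, D)
    dr = d_raw[agent]
    mask = dr > 0
    v = np.zeros(positions.shape[1])
    if mask.any():
        s = social_force(d_scaled[agent][mask], f_intensity, l_scale)
        coef = c * (_UB - _LB) / 2.0 * s / dr[mask]
        v = coef @ diff[mask]
    return c * v + attractor


def binarize(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Probabilistic set rule: bit = 1 iff u < logistic(v), u ~ U(0, 1)."""
    v = np.asarray(v, dtype=float)
    return (rng.random(v.shape[0]) < expit(v)).astype(np.uint8)


def optimize(fitness_fn, D: int, params: GOAParams, variant: str = "ktgoa",
             memoize: bool = True, raw_transfer: bool = False) -> SwarmResult:
    """Run the binary swarm loop and return the elitist best.

    The initial population is i.i.d. Bernoulli(0.5) except agent 0, which is
    the all-ones vector.  ``fitness_fn`` must be a total, deterministic
    function of the bit vector; with ``memoize`` repeated positions are not
    re-evaluated.  The elitist best never degrades, so ``history`` is
    monotone non-decreasing.

    By default the displacement is centered on the box midpoint and sharpened
    by the decaying coefficient ``c`` before the S-shaped transfer,
    ``u = (v - 1/2) / c``, so early iterations explore broadly and late
    iterations freeze onto the attractors; without this the set-rule transfer
    resamples every bit near Bernoulli(0.5) forever and the swarm cannot
    converge.  ``raw_transfer=True`` feeds ``v`` to the transfer unscaled.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if variant not in ("bgoa", "ktgoa"):
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(params.seed)
    P = params.pop_size
    positions = rng.integers(0, 2, size=(P, D), dtype=np.uint8)
    positions[0] = 1

    cache: dict[bytes, float] = {}
    n_eval = 0

    def evaluate(pop: np.ndarray, iteration: int) -> np.ndarray:
        nonlocal n_eval
        out = np.empty(pop.shape[0])
        for i, bits in enumerate(pop):
            key = bits.tobytes()
            if memoize and key in cache:
                out[i] = cache[key]
                continue
            try:
                val = float(fitness_fn(bits.copy()))
            except Exception as exc:
                raise RuntimeError(
                    f"fitness evaluation failed at iteration {iteration}, agent {i}"
                ) from exc
            n_eval += 1
            if memoize:
                cache[key] = val
            out[i] = val
        return out

    fitnesses = evaluate(positions, 0)
    best_idx = int(np.argmax(fitnesses))
    best_position = positions[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])
    history = [best_fitness]
    trace = [{
        "iteration": 0,
        "best_fitness": best_fitness,
        "mean_fitness": float(fitnesses.mean()),
        "n_active_bits_best": int(best_position.sum()),
    }]

    for it in range(1, params.max_iter + 1):
        c = coefficient_schedule(it, params)
        distances = _scaled_distances(positions)
        pop_best = int(np.argmax(fitnesses))
        new_positions = np.empty_like(positions)
        for i in range(P):
            # Both variants draw the tournament so rng consumption matches.
            winner = tournament_select(fitnesses, params.k, rng)
            attr_idx = winner if variant == "ktgoa" else pop_best
            v = goa_displacement(positions, i, positions[attr_idx], c,
                                 params.f_intensity, params.l_scale, distances)
            u = v if raw_transfer else (v - (_UB + _LB) / 2.0) / c
            new_positions[i] = binarize(u, rng)
        positions = new_positions
        fitnesses = evaluate(positions, it)
        it_best = int(np.argmax(fitnesses))
        if fitnesses[it_best] > best_fitness:
            best_fitness = float(fitnesses[it_best])
            best_position = positions[it_best].copy()
        history.append(best_fitness)
        trace.append({
            "iteration": it,
            "best_fitness": best_fitness,
            "mean_fitness": float(fitnesses.mean()),
            "n_active_bits_best": int(best_position.sum()),
        })

    return SwarmResult(best_position=best_position, best_fitness=best_fitness,
                       history=np.asarray(history), trace=trace, n_evaluations=n_eval)
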