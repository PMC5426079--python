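"""Particle swarm optimization over the (k, alpha) box.

Standard global-best PSO with linearly decaying inertia,

    v <- w*v + c1*r1*(p_i - x) + c2*r2*(p_g - x),    x <- x + v,
    w(t) = w_max - (w_max - w_min) * t / t_max,

with positions clamped to the search box (a clamped component's velocity is
zeroed) and convergence declared when the global best position stalls for
``patience`` consecutive generations. The swarm is initialized on a
deterministic uniform grid by default so that the objective's normalization
factors depend only on the image; seeded uniform-random initialization is
available as a config option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SwarmConfig

logger = logging.getLogger(__name__)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = -math.inf


def inertia_weight(t: int, cfg: SwarmConfig) -> float:
    """Linearly decaying inertia: w_max at t=0 down to w_min at t=t_max."""
    return cfg.w_max - (cfg.w_max - cfg.w_min) * t / cfg.t_max


def _bounds(cfg: SwarmConfig) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([cfg.k_bounds[0], cfg.alpha_bounds[0]])
    hi = np.array([cfg.k_bounds[1], cfg.alpha_bounds[1]])
    return lo, hi


def grid_shape(n_p: int) -> tuple[int, int] | None:
    """Factor n_p into an (n_k, n_alpha) grid.

    The k axis gets the divisor of n_p nearest sqrt(2*n_p) (the k range is
    the dominant direction of the search box), e.g. 20x10 for n_p=200,
    10x5 for 50, 2x2 for 4. Returns None when no non-degenerate
    factorization exists (then callers fall back to random placement).
    """
    divisors = [d for d in range(2, n_p // 2 + 1) if n_p % d == 0]
    if not divisors:
        return None
    target = math.sqrt(2 * n_p)
    n_k = min(divisors, key=lambda d: (abs(d - target), d))
    return n_k, n_p // n_k


def initialize_swarm(cfg: SwarmConfig) -> list[Particle]:
    """Place n_p particles in the box with zero initial velocity.

    Grid mode puts them at the centers of an n_k x n_alpha lattice of equal
    cells; the placement is deterministic, so repeated calls with the same
    config yield identical swarms.
    """
    lo, hi = _bounds(cfg)
    if cfg.init == "grid":
        shape = grid_shape(cfg.n_p)
        if shape is None:
            logger.warning(
                "swarm size %d has no grid factorization; falling back to "
                "seeded random initialization", cfg.n_p,
            )
            return _random_swarm(cfg, lo, hi)
        n_k, n_a = shape
        ks = lo[0] + (np.arange(n_k) + 0.5) / n_k * (hi[0] - lo[0])
        als = lo[1] + (np.arange(n_a) + 0.5) / n_a * (hi[1] - lo[1])
        positions = [np.array([k, a]) for k in ks for a in als]
    else:
        return _random_swarm(cfg, lo, hi)
    return [
        Particle(position=p, velocity=np.zeros(2), best_position=p.copy())
        for p in positions
    ]


def _random_swarm(cfg: SwarmConfig, lo: np.ndarray, hi: np.ndarray) -> list[Particle]:
    rng = np.random.default_rng(cfg.seed)
    pos = lo + rng.random((cfg.n_p, 2)) * (hi - lo)
    return [
        Particle(position=p, velocity=np.zeros(2), best_position=p.copy())
        for p in pos
    ]


def update_particle(
    p: Particle,
    p_g: np.ndarray,
    w: float,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """One velocity/position update, in place, with box clamping.

    r1 and r2 are drawn independently per dimension; a component pushed
    outside the box is clamped to the bound and its velocity zeroed.
    """
    lo, hi = _bounds(cfg)
    r1 = rng.random(2)
    r2 = rng.random(2)
    p.velocity = (
        w * p.velocity
        + cfg.c1 * r1 * (p.best_position - p.position)
        + cfg.c2 * r2 * (p_g - p.position)
    )
    new_pos = p.position + p.velocity
    clamped = np.clip(new_pos, lo, hi)
    p.velocity = np.where(clamped == new_pos, p.velocity, 0.0)
    p.position = clamped


@dataclass
class OptimizationTrace:
    """Per-generation record of the global best; fitness is non-decreasing."""

    records: list[dict] = field(default_factory=list)

    def append(self, t: int, w: float, p_g: np.ndarray, f_g: float) -> None:
        self.records.append(
            {"generation": t, "w": w, "k_best": float(p_g[0]),
             "alpha_best": float(p_g[1]), "f_best": float(f_g)}
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def best_fitness(self) -> float:
        return self.records[-1]["f_best"]


def optimize(
    fitness,
    cfg: SwarmConfig,
    on_init=None,
) -> tuple[np.ndarray, OptimizationTrace]:
    """Maximize ``fitness(position)`` over the (k, alpha) box.

    ``on_init``, when given, receives the (n_p, 2) array of initial
    positions before the first fitness call — the hook the pipeline uses to
    fix the objective's normalization factors from the initial swarm.

    Stops when the global best position has moved less than 1e-9 (in
    box-normalized coordinates) for ``patience`` consecutive generations,
    or at t_max. Raises on non-finite fitness values.
    """
    lo, hi = _bounds(cfg)
    span = hi - lo
    swarm = initialize_swarm(cfg)
    rng = np.random.default_rng(cfg.seed)

    if on_init is not None:
        on_init(np.array([p.position for p in swarm]))

    def _eval(pos: np.ndarray) -> float:
        f = float(fitness(pos))
        if not math.isfinite(f):
            raise ValueError(f"non-finite fitness {f!r} at k={pos[0]}, alpha={pos[1]}")
        return f

    p_g = None
    f_g = -math.inf
    for part in swarm:
        f = _eval(part.position)
        part.best_fitness = f
        if f > f_g:
            f_g = f
            p_g = part.position.copy()

    trace = OptimizationTrace()
    trace.append(0, inertia_weight(0, cfg), p_g, f_g)

    stagnant = 0
    for t in range(1, cfg.t_max + 1):
        w = inertia_weight(t, cfg)
        prev_pg = p_g.copy()
        for part in swarm:
            update_particle(part, p_g, w, cfg, rng)
            f = _eval(part.position)
            if f > part.best_fitness:
                part.best_fitness = f
                part.best_position = part.position.copy()
            if f > f_g:
                f_g = f
                p_g = part.position.copy()
        trace.append(t, w, p_g, f_g)
        if np.all(np.abs(p_g - prev_pg) / span < 1e-9):
            stagnant += 1
        else:
            stagnant = 0
        if stagnant >= cfg.patience:
            break
    return p_g, trace
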