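"""Global-best particle swarm optimization over a box-bounded search space.

Velocities follow v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x) with the
constriction-equivalent defaults w = 0.729, c1 = c2 = 1.49445; positions are
reflected at the bounds and velocities clamped to half the box range.  The
recorded global-best fitness is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PSOConfig", "PSOResult", "pso_optimize"]


@dataclass
class PSOConfig:
    swarm_size: int = 20
    iterations: int = 15
    lower: np.ndarray = field(default_factory=lambda: np.zeros(3))
    upper: np.ndarray = field(default_factory=lambda: np.ones(3))
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_clamp: float = 0.5     # fraction of the box range
    seed: int = 0
    x0: np.ndarray | None = None    # optional warm-start rows for the swarm

    def __post_init__(self):
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bound shapes differ")
        if not np.all(np.isfinite(self.lower)) or not np.all(np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if not np.all(self.lower < self.upper):
            raise ValueError("need lower < upper in every dimension")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    gbest_trace: np.ndarray          # per-iteration global best (non-increasing)
    mean_trace: np.ndarray           # per-iteration swarm mean fitness
    fitness_matrix: np.ndarray       # (iterations, swarm_size)
    positions_visited: np.ndarray    # (iterations, swarm_size, dim)


def _reflect(x, lo, hi):
    """Reflect positions into [lo, hi] (handles multiple bounces)."""
    rng_ = hi - lo
    x = np.where(rng_ > 0, x, lo)
    period = 2.0 * rng_
    xm = np.mod(x - lo, period)
    xm = np.where(xm > rng_, period - xm, xm)
    return lo + xm


def pso_optimize(fitness_fn, config: PSOConfig) -> PSOResult:
    """Minimize ``fitness_fn(position, particle_id, iteration) -> float``.

    The callback signature carries the particle id and iteration so the
    caller can derive reproducible per-evaluation seeds.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dim = len(cfg.lower)
    span = cfg.upper - cfg.lower
    vmax = cfg.velocity_clamp * span

    x = cfg.lower + rng.random((cfg.swarm_size, dim)) * span
    if cfg.x0 is not None:
        x0 = np.atleast_2d(np.asarray(cfg.x0, float))
        x[: len(x0)] = _reflect(x0, cfg.lower, cfg.upper)
    v = (rng.random((cfg.swarm_size, dim)) - 0.5) * span
    pbest = x.copy()
    pbest_f = np.full(cfg.swarm_size, np.inf)
    gbest = x[0].copy()
    gbest_f = np.inf

    fit_mat = np.zeros((cfg.iterations, cfg.swarm_size))
    pos_hist = np.zeros((cfg.iterations, cfg.swarm_size, dim))
    gtrace, mtrace = [], []
    for it in range(cfg.iterations):
        for j in range(cfg.swarm_size):
            f = float(fitness_fn(x[j], j, it))
            fit_mat[it, j] = f
            if f < pbest_f[j]:
                pbest_f[j] = f
                pbest[j] = x[j].copy()
            if f < gbest_f:
                gbest_f = f
                gbest = x[j].copy()
        pos_hist[it] = x
        if not np.any(np.isfinite(fit_mat[it])):
            raise RuntimeError(
                f"all particle fitnesses non-finite at iteration {it}: "
                f"{fit_mat[:it + 1]!r}")
        gtrace.append(gbest_f)
        mtrace.append(float(np.mean(fit_mat[it][np.isfinite(fit_mat[it])])))
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        v = (cfg.inertia * v + cfg.cognitive * r1 * (pbest - x)
             + cfg.social * r2 * (gbest - x))
        v = np.clip(v, -vmax, vmax)
        x = _reflect(x + v, cfg.lower, cfg.upper)
    return PSOResult(gbest, gbest_f, np.array(gtrace), np.array(mtrace),
                     fit_mat, pos_hist)
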