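"""Population-based optimizer with position/velocity updates and clan migration.

The core update per particle ``i`` (maximization convention) is::

    V_i <- w * V_i + c1 * r1 * (pbest_i - x_i) + c2 * r2 * (gbest - x_i)
    x_i <- x_i + V_i

with fresh uniform draws ``r1``, ``r2`` per particle per dimension, positions
clamped to the search box and velocities clamped to half the box width.  An
optional nomadic layer splits the swarm into clans and periodically
re-scatters the worst clan uniformly around the incumbent global best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SwarmConfig", "SwarmState", "init_swarm", "step", "optimize"]


@dataclass
class SwarmConfig:
    swarm_size: int = 30
    dims: int = 1
    bounds: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    w: float = 0.729
    c1: float = 1.494
    c2: float = 1.494
    max_iters: int = 100
    seed: int = 0
    migration_every: int = 0  # 0 disables the nomadic layer
    n_clans: int = 3
    migration_radius_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if len(self.bounds) != self.dims:
            raise ValueError("bounds length must equal dims")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")
        if min(self.w, self.c1, self.c2) < 0:
            raise ValueError("w, c1, c2 must be nonnegative")


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    pbest: np.ndarray
    pbest_fitness: np.ndarray
    gbest: np.ndarray
    gbest_fitness: float
    iteration: int
    rng: np.random.Generator
    frozen: np.ndarray  # particles disabled after a non-finite fitness


def _bounds_arrays(cfg: SwarmConfig) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(cfg.bounds, dtype=float)
    return b[:, 0], b[:, 1]


def init_swarm(cfg: SwarmConfig, fitness) -> SwarmState:
    """Seeded uniform initialization; velocities start at zero."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _bounds_arrays(cfg)
    pos = rng.uniform(lo, hi, size=(cfg.swarm_size, cfg.dims))
    fit = np.array([fitness(p) for p in pos], dtype=float)
    bad = ~np.isfinite(fit)
    if np.any(bad):
        raise ValueError(f"non-finite fitness at initial point {pos[np.argmax(bad)]}")
    g = int(fit.argmax())
    return SwarmState(
        positions=pos,
        velocities=np.zeros_like(pos),
        pbest=pos.copy(),
        pbest_fitness=fit,
        gbest=pos[g].copy(),
        gbest_fitness=float(fit[g]),
        iteration=0,
        rng=rng,
        frozen=np.zeros(cfg.swarm_size, dtype=bool),
    )


def step(
    state: SwarmState,
    cfg: SwarmConfig,
    fitness,
    r1: np.ndarray | None = None,
    r2: np.ndarray | None = None,
) -> SwarmState:
    """Advance the swarm one iteration in place (and return it).

    ``r1``/``r2`` override the per-particle per-dimension uniform draws —
    used by deterministic unit tests; by default they come from the state's
    random stream.
    """
    n, d = state.positions.shape
    if r1 is None:
        r1 = state.rng.random((n, d))
    if r2 is None:
        r2 = state.rng.random((n, d))
    lo, hi = _bounds_arrays(cfg)
    vmax = (hi - lo) / 2.0

    v = (
        cfg.w * state.velocities
        + cfg.c1 * r1 * (state.pbest - state.positions)
        + cfg.c2 * r2 * (state.gbest[None, :] - state.positions)
    )
    v = np.clip(v, -vmax, vmax)
    live = ~state.frozen
    state.velocities[live] = v[live]
    state.positions[live] = np.clip(state.positions[live] + v[live], lo, hi)

    for i in np.flatnonzero(live):
        f = float(fitness(state.positions[i]))
        if not np.isfinite(f):
            warnings.warn(f"freezing particle {i}: non-finite fitness", stacklevel=2)
            state.frozen[i] = True
            continue
        if f > state.pbest_fitness[i]:
            state.pbest_fitness[i] = f
            state.pbest[i] = state.positions[i].copy()
            if f > state.gbest_fitness:
                state.gbest_fitness = f
                state.gbest = state.positions[i].copy()
    state.iteration += 1
    return state


def _migrate(state: SwarmState, cfg: SwarmConfig, fitness) -> None:
    """Re-scatter the worst clan uniformly around the global best."""
    lo, hi = _bounds_arrays(cfg)
    clans = np.array_split(np.arange(cfg.swarm_size), cfg.n_clans)
    worst = min(clans, key=lambda idx: state.pbest_fitness[idx].max())
    radius = (hi - lo) * cfg.migration_radius_frac
    for i in worst:
        if state.frozen[i]:
            continue
        newp = np.clip(
            state.gbest + state.rng.uniform(-radius, radius), lo, hi
        )
        f = float(fitness(newp))
        if not np.isfinite(f):
            continue
        state.positions[i] = newp
        state.velocities[i] = 0.0
        if f > state.pbest_fitness[i]:
            state.pbest_fitness[i] = f
            state.pbest[i] = newp.copy()
            if f > state.gbest_fitness:
                state.gbest_fitness = f
                state.gbest = newp.copy()


def optimize(fitness, cfg: SwarmConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the swarm for ``max_iters`` iterations.

    Returns ``(best point, best fitness, trace)`` where ``trace[j]`` is the
    global-best fitness after iteration ``j + 1`` (monotone nondecreasing by
    construction).
    """
    state = init_swarm(cfg, fitness)
    trace = np.empty(cfg.max_iters)
    for it in range(cfg.max_iters):
        step(state, cfg, fitness)
        if cfg.migration_every > 0 and (it + 1) % cfg.migration_every == 0:
            _migrate(state, cfg, fitness)
        trace[it] = state.gbest_fitness
    return state.gbest.copy(), state.gbest_fitness, trace
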