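"""Leader-follower resource-allocation game and bilevel solvers.

One leader commits a bounded scalar strategy ``x`` (read as a bandwidth
share); each of ``N`` followers best-responds with ``y_i`` inside its own
box.  The default, closed-form-solvable family is::

    U_F^i(x, y) = p_i * x * y - q_i * y^2 / 2 - r_i * y          (q_i > 0)
    U_L(x, y)   = sum_i [ lambda1 * A_i(y_i) - lambda2 * C_i(x, y_i) ]
    A_i(y)      = a_i * (1 - exp(-k_i * y))
    C_i(x, y)   = e_i * y + g_i * x

All functional forms are pluggable via callables on :class:`GameSpec`; the
solvers only rely on follower utilities being strictly concave in ``y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize

__all__ = [
    "GameSpec",
    "Equilibrium",
    "follower_utility",
    "leader_utility",
    "follower_best_response",
    "solve_stackelberg",
    "validate_game",
]


@dataclass
class GameSpec:
    leader_bounds: tuple[float, float] = (0.0, 1.0)
    n_followers: int = 1
    follower_bounds: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 1.0)])
    lambda1: float = 1.0
    lambda2: float = 1.0
    accuracy_params: list[tuple[float, float]] = field(default_factory=lambda: [(1.0, 1.0)])
    cost_params: list[tuple[float, float]] = field(default_factory=lambda: [(0.1, 0.1)])
    follower_utility_params: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1.0, 1.0, 0.0)]
    )
    # pluggable overrides; signatures: f(x, y, i) / a(y, i) / c(x, y, i)
    follower_utility_fn: object = None
    accuracy_fn: object = None
    cost_fn: object = None
    response_noise_halfwidth: float = 0.0
    noise_seed: int = 0

    def to_json(self) -> str:
        doc = asdict(self)
        for k in ("follower_utility_fn", "accuracy_fn", "cost_fn"):
            doc[k] = None if getattr(self, k) is None else "<callable>"
        return json.dumps(doc, indent=2)


@dataclass
class Equilibrium:
    x_star: float
    y_star: list[float]
    leader_utility: float
    follower_utilities: list[float]
    solver: str
    residual: float
    converged: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _check_index(game: GameSpec, i: int) -> None:
    if not 0 <= i < game.n_followers:
        raise IndexError(f"follower index {i} out of range [0, {game.n_followers})")


def follower_utility(game: GameSpec, x: float, y_i: float, i: int) -> float:
    """Utility of follower ``i`` under leader strategy ``x``."""
    _check_index(game, i)
    if game.follower_utility_fn is not None:
        return float(game.follower_utility_fn(x, y_i, i))
    p, q, r = game.follower_utility_params[i]
    return p * x * y_i - q * y_i**2 / 2.0 - r * y_i


def _accuracy(game: GameSpec, y: float, i: int) -> float:
    if game.accuracy_fn is not None:
        return float(game.accuracy_fn(y, i))
    a, k = game.accuracy_params[i]
    return a * (1.0 - np.exp(-k * y))


def _cost(game: GameSpec, x: float, y: float, i: int) -> float:
    if game.cost_fn is not None:
        return float(game.cost_fn(x, y, i))
    e, g = game.cost_params[i]
    return e * y + g * x


def leader_utility(game: GameSpec, x: float, y: np.ndarray | list[float]) -> float:
    """Leader payoff: weighted accuracy sum minus weighted cost sum."""
    y = np.asarray(y, dtype=float)
    if y.shape != (game.n_followers,):
        raise ValueError(f"expected {game.n_followers} follower strategies, got {y.shape}")
    total = 0.0
    for i, yi in enumerate(y):
        total += game.lambda1 * _accuracy(game, yi, i) - game.lambda2 * _cost(game, x, yi, i)
    return float(total)


def follower_best_response(game: GameSpec, x: float, i: int, tol: float = 1e-8) -> float:
    """Argmax of follower ``i``'s utility over its strategy box.

    Closed form for the default quadratic family; bounded scalar maximization
    otherwise (with a numeric concavity probe first).
    """
    _check_index(game, i)
    lo, hi = game.follower_bounds[i]
    if game.follower_utility_fn is None:
        p, q, r = game.follower_utility_params[i]
        if q <= 0:
            raise ValueError(f"follower {i}: q={q} violates strict concavity")
        y = float(np.clip((p * x - r) / q, lo, hi))
    else:
        grid = np.linspace(lo, hi, 101)
        vals = np.array([follower_utility(game, x, g, i) for g in grid])
        if np.any(np.diff(vals, 2) > 1e-6 * max(1.0, np.abs(vals).max())):
            raise ValueError(f"follower {i}: utility not concave on [{lo}, {hi}]")
        res = optimize.minimize_scalar(
            lambda yy: -follower_utility(game, x, yy, i),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        y = float(res.x)
        # the bounded method can stall a hair inside the box; snap if better
        for cand in (lo, hi):
            if follower_utility(game, x, cand, i) > follower_utility(game, x, y, i):
                y = cand
    if game.response_noise_halfwidth > 0:
        rng = np.random.default_rng(game.noise_seed + i)
        y = float(np.clip(y + rng.uniform(-1, 1) * game.response_noise_halfwidth, lo, hi))
    return y


def _best_responses(game: GameSpec, x: float, tol: float = 1e-8) -> np.ndarray:
    return np.array([follower_best_response(game, x, i, tol) for i in range(game.n_followers)])


def _reduced_objective(game: GameSpec, x: float, tol: float = 1e-8) -> float:
    return leader_utility(game, x, _best_responses(game, x, tol))


def _solve_closed_form(game: GameSpec, tol: float) -> float:
    """Piecewise-analytic leader optimum for the default family.

    Within a region where the set of clipped followers is constant, the
    reduced objective is smooth and its derivative strictly decreasing, so a
    sign change brackets the unique interior stationary point.
    """
    if game.follower_utility_fn or game.accuracy_fn or game.cost_fn:
        raise ValueError("closed_form solver supports only the default family")
    xlo, xhi = game.leader_bounds

    def dphi(x: float) -> float:
        total = 0.0
        for i in range(game.n_followers):
            p, q, r = game.follower_utility_params[i]
            lo, hi = game.follower_bounds[i]
            a, k = game.accuracy_params[i]
            e, g = game.cost_params[i]
            y = (p * x - r) / q
            if lo < y < hi:  # interior: dy/dx = p/q
                dy = p / q
                total += game.lambda1 * a * k * np.exp(-k * y) * dy - game.lambda2 * (e * dy + g)
            else:  # clipped: y constant
                total += -game.lambda2 * g
        return total

    # breakpoints where any follower's response hits a box edge
    points = {xlo, xhi}
    for i in range(game.n_followers):
        p, q, r = game.follower_utility_params[i]
        lo, hi = game.follower_bounds[i]
        if p != 0:
            for edge in (lo, hi):
                xb = (q * edge + r) / p
                if xlo < xb < xhi:
                    points.add(float(xb))
    knots = sorted(points)
    candidates = list(knots)
    for a_, b_ in zip(knots[:-1], knots[1:]):
        eps = max(1e-12, (b_ - a_) * 1e-9)
        fa, fb = dphi(a_ + eps), dphi(b_ - eps)
        if fa > 0 > fb:
            candidates.append(float(optimize.brentq(dphi, a_ + eps, b_ - eps, xtol=tol)))
    vals = [(_reduced_objective(game, x, tol), x) for x in candidates]
    return max(vals)[1]


def _solve_grid(game: GameSpec, tol: float) -> float:
    xlo, xhi = game.leader_bounds
    grid = np.linspace(xlo, xhi, 2001)
    vals = np.array([_reduced_objective(game, x, tol) for x in grid])
    j = int(vals.argmax())
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    if hi <= lo:
        return float(grid[j])
    res = optimize.minimize_scalar(
        lambda x: -_reduced_objective(game, x, tol),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": min(tol, 1e-6)},
    )
    return float(res.x) if -res.fun >= vals[j] else float(grid[j])


def _solve_npo(game: GameSpec, tol: float) -> float:
    from .npo import SwarmConfig, optimize as swarm_optimize

    cfg = SwarmConfig(
        swarm_size=24,
        dims=1,
        bounds=[game.leader_bounds],
        max_iters=200,
        seed=game.noise_seed,
    )
    best, _, _ = swarm_optimize(lambda v: _reduced_objective(game, float(v[0]), tol), cfg)
    return float(best[0])


def solve_stackelberg(game: GameSpec, solver: str = "grid", tol: float = 1e-6) -> Equilibrium:
    """Solve the bilevel game: leader optimum anticipating exact best responses."""
    report = validate_game(game)
    if report["violations"]:
        raise ValueError(f"invalid game: {report['violations']}")
    if solver == "closed_form":
        x_star = _solve_closed_form(game, tol)
    elif solver == "grid":
        x_star = _solve_grid(game, tol)
    elif solver == "npo":
        x_star = _solve_npo(game, tol)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    y_star = _best_responses(game, x_star, tol)
    follower_utils = [follower_utility(game, x_star, y_star[i], i) for i in range(game.n_followers)]
    # residual: how far each returned follower strategy is from its true optimum
    residual = max(
        abs(
            follower_utility(game, x_star, follower_best_response(game, x_star, i, tol), i)
            - follower_utils[i]
        )
        for i in range(game.n_followers)
    )
    return Equilibrium(
        x_star=float(x_star),
        y_star=[float(v) for v in y_star],
        leader_utility=leader_utility(game, x_star, y_star),
        follower_utilities=[float(v) for v in follower_utils],
        solver=solver,
        residual=float(residual),
        converged=bool(residual <= max(tol, 1e-6)),
    )


def validate_game(game: GameSpec) -> dict:
    """Structural checks; returns ``{"ok": bool, "violations": [...]}``."""
    v: list[str] = []
    lo, hi = game.leader_bounds
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        v.append(f"leader bounds [{lo}, {hi}] empty or non-finite")
    if len(game.follower_bounds) != game.n_followers:
        v.append("follower_bounds length != n_followers")
    for i, (flo, fhi) in enumerate(game.follower_bounds):
        if not (np.isfinite(flo) and np.isfinite(fhi)) or flo > fhi:
            v.append(f"follower {i} bounds [{flo}, {fhi}] empty or non-finite")
    if game.lambda1 < 0 or game.lambda2 < 0:
        v.append("lambda weights must be nonnegative")
    if game.follower_utility_fn is None:
        if len(game.follower_utility_params) != game.n_followers:
            v.append("follower_utility_params length != n_followers")
        else:
            for i, (p, q, r) in enumerate(game.follower_utility_params):
                if q <= 0:
                    v.append(f"follower {i}: q={q} <= 0 breaks strict concavity")
    else:
        # numeric concavity probe on a grid for each follower at a few x values
        for i in range(game.n_followers):
            flo, fhi = game.follower_bounds[i]
            if flo >= fhi or not np.isfinite(flo) or not np.isfinite(fhi):
                continue
            grid = np.linspace(flo, fhi, 41)
            for x in np.linspace(*game.leader_bounds, 3):
                vals = np.array([follower_utility(game, x, g, i) for g in grid])
                if np.any(np.diff(vals, 2) > 1e-6 * max(1.0, np.abs(vals).max())):
                    v.append(f"follower {i}: concavity probe failed at x={x:.3g}")
                    break
    return {"ok": not v, "violations": v}
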