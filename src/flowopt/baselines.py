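"""Gradient-free baseline optimizers and the benchmark harness.

All methods maximize the steady-state outlet imine concentration over the
bounded decision space (residence time, equivalent ratio, temperature) and
report a common :class:`OptimizationResult` with exact evaluation
accounting: every outlet evaluation of every method is logged.

* :func:`nelder_mead_optimize` -- bound-constrained downhill simplex
  (deterministic, start-point sensitive; bounds handled by projection).
* :func:`snobfit_optimize` -- a seeded branch-and-fit global optimizer:
  space-filling initial design, then alternating local quadratic-surrogate
  steps around the incumbent and maximin exploration points.  It is a
  simplified branch-and-fit, not a bit-exact SNOBFIT re-implementation.
* :func:`grid_search` -- exhaustive Cartesian grid, the global-optimum
  oracle for dominance checks.
* :func:`benchmark` -- runs the requested methods (including a DDPG agent
  wrapped through the same accounting) and emits a comparison table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ddpg import FlowReactorEnv, TrainingConfig, train
from .reactor import ConditionBounds, ReactionConditions, ReactorModel

__all__ = [
    "BudgetExhausted",
    "BudgetedEnvironment",
    "OptimizationResult",
    "nelder_mead_optimize",
    "snobfit_optimize",
    "grid_search",
    "benchmark",
]


class BudgetExhausted(RuntimeError):
    """Raised by a budgeted environment when its evaluation budget is spent."""


class BudgetedEnvironment:
    """Wraps an outlet evaluator with an exact call counter, a trajectory
    log, and an optional evaluation budget."""

    def __init__(self, env, budget: int | None = None):
        if callable(env):
            self._fn = env
        elif hasattr(env, "outlet_c3"):
            self._fn = env.outlet_c3
        else:
            raise TypeError("env must be callable or expose outlet_c3(x)")
        self.budget = budget
        self.trajectory: list[tuple[np.ndarray, float]] = []

    @property
    def n_evaluations(self) -> int:
        return len(self.trajectory)

    def evaluate(self, x) -> float:
        if self.budget is not None and self.n_evaluations >= self.budget:
            raise BudgetExhausted(f"budget of {self.budget} evaluations spent")
        x = np.asarray(x, dtype=float).copy()
        c3 = float(self._fn(x))
        self.trajectory.append((x, c3))
        return c3

    def best(self) -> tuple[np.ndarray, float]:
        if not self.trajectory:
            raise RuntimeError("no evaluations recorded")
        i = int(np.argmax([c for _, c in self.trajectory]))
        return self.trajectory[i]

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(x[0], x[1], x[2], c) for x, c in self.trajectory],
            columns=["res_t", "er", "T_K", "c3_M"],
        )


@dataclass
class OptimizationResult:
    """Common output of every self-optimization method."""

    method: str
    x0: np.ndarray | None
    best_conditions: ReactionConditions
    best_c3: float
    n_evaluations: int
    trajectory: pd.DataFrame
    complete: bool = True

    def row(self) -> dict:
        return {
            "method": self.method,
            "x0": "" if self.x0 is None else np.array2string(np.asarray(self.x0), precision=3),
            "n_evaluations": self.n_evaluations,
            "res_t": self.best_conditions.res_t,
            "er": self.best_conditions.er,
            "T_K": self.best_conditions.temp,
            "c3_M": self.best_c3,
            "complete": self.complete,
        }


def _result(method: str, benv: BudgetedEnvironment, x0=None, complete=True) -> OptimizationResult:
    xb, cb = benv.best()
    return OptimizationResult(
        method=method,
        x0=None if x0 is None else np.asarray(x0, dtype=float),
        best_conditions=ReactionConditions.from_array(xb),
        best_c3=cb,
        n_evaluations=benv.n_evaluations,
        trajectory=benv.trajectory_frame(),
        complete=complete,
    )


def _as_budgeted(env, budget) -> BudgetedEnvironment:
    return env if isinstance(env, BudgetedEnvironment) else BudgetedEnvironment(env, budget)


def nelder_mead_optimize(
    env,
    x0,
    bounds: ConditionBounds | None = None,
    budget: int | None = 200,
    xatol: float = 1e-4,
    fatol: float = 1e-8,
) -> OptimizationResult:
    """Maximize the outlet concentration by bound-constrained downhill
    simplex starting from ``x0``.

    Candidate points are projected onto the box before evaluation, so every
    evaluated point is feasible.  Deterministic for a given start; exhausting
    the budget returns the best point so far flagged incomplete.
    """
    bounds = bounds or ConditionBounds()
    x0 = np.asarray(x0, dtype=float)
    if not bounds.contains(x0):
        raise ValueError(f"start point {x0} outside bounds")
    benv = _as_budgeted(env, budget)

    def neg(x):
        return -benv.evaluate(bounds.clip(x))

    complete = True
    try:
        minimize(
            neg,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(bounds.lower, bounds.upper)),
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxfev": benv.budget if benv.budget is not None else 10**6,
            },
        )
    except BudgetExhausted:
        complete = False
    return _result("nelder-mead", benv, x0=x0, complete=complete)


def _space_filling(rng: np.random.Generator, lower, upper, n: int) -> np.ndarray:
    """Latin-hypercube design over the box (seeded)."""
    d = lower.size
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T + rng.uniform(0, 1, (n, d))) / n
    return lower + u * (upper - lower)


def _fit_diag_quadratic(pts: np.ndarray, vals: np.ndarray):
    """Least-squares fit of f ~ b0 + sum_i (b_i x_i + q_i x_i^2)."""
    a = np.hstack([np.ones((pts.shape[0], 1)), pts, pts**2])
    coef, *_ = np.linalg.lstsq(a, vals, rcond=None)
    d = pts.shape[1]
    return coef[0], coef[1 : 1 + d], coef[1 + d :]


def snobfit_optimize(
    env,
    bounds: ConditionBounds | None = None,
    budget: int = 250,
    seed: int = 0,
    n_initial: int | None = None,
    local_fraction: float = 0.5,
    trust_fraction: float = 0.15,
) -> OptimizationResult:
    """Branch-and-fit global maximization of the outlet concentration.

    Starts from a seeded Latin-hypercube design of ``10 * dim`` points, then
    alternates (a) local steps -- a diagonal quadratic surrogate fitted to
    the neighbors of the incumbent, maximized inside a trust box -- and
    (b) exploration steps -- maximin points filling the least-sampled region
    of the box.  Reproducible under ``seed``.
    """
    bounds = bounds or ConditionBounds()
    rng = np.random.default_rng(seed)
    lower, upper, span = bounds.lower, bounds.upper, bounds.span
    d = lower.size
    n_initial = n_initial if n_initial is not None else 10 * d
    benv = _as_budgeted(env, budget)

    complete = True
    try:
        for x in _space_filling(rng, lower, upper, min(n_initial, budget)):
            benv.evaluate(x)
        step = 0
        while benv.n_evaluations < budget:
            pts = np.array([x for x, _ in benv.trajectory])
            vals = np.array([c for _, c in benv.trajectory])
            if step % 2 == 0 and int(local_fraction * 2) > 0:
                # local branch: quadratic surrogate around the incumbent
                xb = pts[np.argmax(vals)]
                dist = np.linalg.norm((pts - xb) / span, axis=1)
                k = min(max(2 * d + 2, 8), pts.shape[0])
                nbr = np.argsort(dist)[:k]
                _, lin, quad = _fit_diag_quadratic(pts[nbr], vals[nbr])
                lo = np.maximum(lower, xb - trust_fraction * span)
                hi = np.minimum(upper, xb + trust_fraction * span)
                x = np.empty(d)
                for i in range(d):
                    if quad[i] < -1e-12:  # concave: interior vertex
                        x[i] = np.clip(-lin[i] / (2 * quad[i]), lo[i], hi[i])
                    else:  # convex/flat: best box corner of the 1-D model
                        cands = np.array([lo[i], hi[i]])
                        x[i] = cands[np.argmax(lin[i] * cands + quad[i] * cands**2)]
                if np.min(np.linalg.norm((pts - x) / span, axis=1)) < 1e-6:
                    x = bounds.clip(x + 0.01 * span * rng.standard_normal(d))
            else:
                # exploration branch: maximin candidate over the whole box
                cands = rng.uniform(lower, upper, size=(64, d))
                dmin = np.min(
                    np.linalg.norm((cands[:, None, :] - pts[None, :, :]) / span, axis=2),
                    axis=1,
                )
                x = cands[np.argmax(dmin)]
            benv.evaluate(x)
            step += 1
    except BudgetExhausted:
        complete = False
    return _result("snobfit", benv, complete=complete)


def grid_search(
    env,
    resolution=(20, 20, 20),
    bounds: ConditionBounds | None = None,
) -> OptimizationResult:
    """Exhaustive Cartesian grid over the decision box -- the global-optimum
    oracle.  Evaluates ``prod(resolution)`` points and returns the exact
    argmax of the evaluated set."""
    bounds = bounds or ConditionBounds()
    if any(r < 2 for r in resolution):
        raise ValueError("need at least 2 points per axis")
    benv = _as_budgeted(env, None)
    axes = [np.linspace(lo, hi, r) for lo, hi, r in zip(bounds.lower, bounds.upper, resolution)]
    for x in itertools.product(*axes):
        benv.evaluate(np.array(x))
    return _result(f"grid-{'x'.join(map(str, resolution))}", benv)


def ddpg_optimize(
    model: ReactorModel,
    config: TrainingConfig | None = None,
    evaluator: str = "steady-state",
    seed: int = 0,
) -> OptimizationResult:
    """A DDPG training run wrapped through the common accounting: the
    trajectory is every environment evaluation made during training and the
    result is the best condition found."""
    config = config or TrainingConfig()
    env = FlowReactorEnv(model, evaluator=evaluator)
    benv = BudgetedEnvironment(env.outlet_c3)
    # route every outlet evaluation through the budget accountant
    env.outlet_c3 = benv.evaluate
    train(env, config, seed=seed)
    return _result("ddpg", benv)


def benchmark(
    model: ReactorModel | None = None,
    methods=("nelder-mead", "snobfit", "ddpg"),
    evaluator: str = "steady-state",
    seed: int = 0,
    nm_x0=None,
    nm_budget: int = 200,
    snobfit_budget: int = 250,
    ddpg_config: TrainingConfig | None = None,
):
    """Run the requested self-optimization methods head-to-head on fresh
    budgeted environments and emit a comparison table.

    Returns ``(table, results)``: one table row and one
    :class:`OptimizationResult` per method.  The default DDPG budget is a
    scaled-down training (20 episodes of 10 steps) so the agent's
    evaluation count is comparable with the gradient-free budgets.
    """
    model = model or ReactorModel()
    nm_x0 = np.asarray(
        nm_x0 if nm_x0 is not None else [0.66, 0.714, 280.55], dtype=float
    )
    results: dict[str, OptimizationResult] = {}
    for m in methods:
        env = FlowReactorEnv(model, evaluator=evaluator)
        if m == "nelder-mead":
            results[m] = nelder_mead_optimize(env.outlet_c3, nm_x0, model.bounds, budget=nm_budget)
        elif m == "snobfit":
            results[m] = snobfit_optimize(env.outlet_c3, model.bounds, budget=snobfit_budget, seed=seed)
        elif m == "ddpg":
            cfg = ddpg_config or TrainingConfig(episodes=20, steps_per_episode=10, seed=seed)
            results[m] = ddpg_optimize(model, cfg, evaluator=evaluator, seed=seed)
        elif m == "grid":
            results[m] = grid_search(env.outlet_c3, bounds=model.bounds)
        else:
            raise ValueError(f"unknown method {m!r}")
    table = pd.DataFrame([r.row() for r in results.values()])
    return table, results


def format_benchmark(table: pd.DataFrame) -> str:
    """Plain-text rendering of the benchmark table."""
    return table.to_string(index=False, float_format=lambda v: f"{v:.4g}")
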