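"""Hyperparameter search and the adaptive dynamic schedule.

Three tools live here:

* :func:`adaptive_value` / :class:`AdaptiveSchedule` -- the linear-decay
  schedule HP_t = max(HP_max - alpha * A_t, HP_min) with training-progress
  metric A_t = N_total * Ep_t + N_t, used to anneal the exploration noise
  and the learning rates during training.
* :func:`bayesian_search` -- sequential model-based hyperparameter
  optimization with a tree-structured Parzen estimator (TPE) sampler:
  observed trials are split at a quantile into "good" and "rest" sets,
  one-dimensional Parzen (Gaussian-mixture) densities l(x) and g(x) are
  built over each set, and the next trial maximizes l(x)/g(x) over a batch
  of candidates drawn from l.
* :func:`ovat_scan` -- one-variable-at-a-time scans producing per-value
  training curves for trial-and-error comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddpg import FlowReactorEnv, TrainingConfig, TrainingHistory, train

__all__ = [
    "AdaptiveSchedule",
    "adaptive_value",
    "default_schedules",
    "HyperparameterSpace",
    "TrialResult",
    "bayesian_search",
    "ovat_scan",
    "training_objective",
]


@dataclass(frozen=True)
class AdaptiveSchedule:
    """Linear decay of one hyperparameter over training progress.

    ``applies_to`` selects the target: "sigma_e", "alpha_actor" or
    "alpha_critic".  ``alpha_decay`` is the per-step decay rate.
    """

    hp_max: float
    hp_min: float
    alpha_decay: float
    applies_to: str = "sigma_e"

    def __post_init__(self):
        if self.hp_min >= self.hp_max:
            raise ValueError("hp_min must be below hp_max")
        if self.alpha_decay <= 0:
            raise ValueError("alpha_decay must be positive")
        if self.applies_to not in ("sigma_e", "alpha_actor", "alpha_critic"):
            raise ValueError(f"cannot schedule {self.applies_to!r}")

    def value(self, ep: int, nt: int, n_total: int) -> float:
        return adaptive_value(self, ep, nt, n_total)


def adaptive_value(sched: AdaptiveSchedule, ep: int, nt: int, n_total: int) -> float:
    """HP_t = max(HP_max - alpha * A_t, HP_min) with A_t = N_total*Ep_t + N_t."""
    if ep < 0 or nt < 0:
        raise ValueError("episode and step indices must be non-negative")
    a_t = n_total * ep + nt
    return max(sched.hp_max - sched.alpha_decay * a_t, sched.hp_min)


def _decay_to_reach(hp_max: float, hp_min: float, total_steps: int, fraction: float = 0.8) -> float:
    """Decay rate such that the floor is reached at ``fraction`` of training."""
    return (hp_max - hp_min) / max(fraction * total_steps, 1.0)


def default_schedules(
    config: TrainingConfig,
    targets: tuple[str, ...] = ("sigma_e",),
    fraction: float = 0.8,
) -> tuple[AdaptiveSchedule, ...]:
    """Schedules for the named hyperparameters, decaying from a high to a
    low value so the floor is reached at ~80% of total training steps.

    Endpoints: sigma_e 0.1 -> 0.01; each learning rate spans its search
    range scaled by a factor of 10 down (0.002 -> 2e-5 for the critic,
    0.001 -> 1e-5 for the actor), so training starts with fast, coarse
    updates and ends with fine ones.
    """
    total = config.episodes * config.steps_per_episode
    space = HyperparameterSpace()
    endpoints = {
        "sigma_e": (0.1, 0.01),
        "alpha_actor": (space.alpha_actor[1] / 10.0, space.alpha_actor[0] / 10.0),
        "alpha_critic": (space.alpha_critic[1] / 10.0, space.alpha_critic[0] / 10.0),
    }
    out = []
    for t in targets:
        hi, lo = endpoints[t]
        out.append(
            AdaptiveSchedule(hp_max=hi, hp_min=lo,
                             alpha_decay=_decay_to_reach(hi, lo, total, fraction),
                             applies_to=t)
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# Bayesian (TPE) search


@dataclass(frozen=True)
class HyperparameterSpace:
    """Box ranges of the five tuned hyperparameters.  Learning rates and the
    exploration noise are searched on a log scale."""

    alpha_critic: tuple[float, float] = (0.0002, 0.02)
    alpha_actor: tuple[float, float] = (0.0001, 0.01)
    gamma: tuple[float, float] = (0.001, 0.999)
    sigma_e: tuple[float, float] = (0.0001, 0.5)
    tau: tuple[float, float] = (0.0001, 1.0)
    log_scale: tuple[str, ...] = ("alpha_critic", "alpha_actor", "sigma_e", "tau")

    def __post_init__(self):
        for name in self.names:
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name}: lower bound must be below upper")

    @property
    def names(self) -> tuple[str, ...]:
        return ("alpha_critic", "alpha_actor", "gamma", "sigma_e", "tau")

    def transform(self, params: dict) -> np.ndarray:
        """Map a parameter dict to the internal (possibly log) search scale."""
        out = []
        for n in self.names:
            v = params[n]
            out.append(math.log(v) if n in self.log_scale else v)
        return np.array(out)

    def inverse(self, x: np.ndarray) -> dict:
        return {
            n: (math.exp(v) if n in self.log_scale else float(v))
            for n, v in zip(self.names, x)
        }

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for n in self.names:
            a, b = getattr(self, n)
            if n in self.log_scale:
                a, b = math.log(a), math.log(b)
            lo.append(a)
            hi.append(b)
        return np.array(lo), np.array(hi)


@dataclass
class TrialResult:
    number: int
    params: dict
    value: float | None
    failed: bool = False


def _parzen_logpdf(x: np.ndarray, centers: np.ndarray, sigma: float, lo: float, hi: float) -> np.ndarray:
    """Log density of a 1-D Parzen mixture with a uniform prior component."""
    z = (x[:, None] - centers[None, :]) / sigma
    comp = np.exp(-0.5 * z**2) / (sigma * math.sqrt(2 * math.pi))
    prior = 1.0 / (hi - lo)
    dens = (comp.sum(axis=1) + prior) / (centers.size + 1)
    return np.log(dens)


def bayesian_search(
    objective,
    space: HyperparameterSpace | None = None,
    n_trials: int = 15,
    seed: int = 0,
    n_startup: int = 8,
    gamma_quantile: float = 0.25,
    n_candidates: int = 24,
):
    """Maximize ``objective(params_dict)`` over the hyperparameter box with
    a TPE sampler.

    The first ``n_startup`` trials are uniform (on the internal scale);
    subsequent trials split completed trials at the ``gamma_quantile`` best,
    fit per-dimension Parzen densities to both groups, draw candidates from
    the good-group density and keep the candidate with the highest
    log l(x) - log g(x).  A failing objective marks the trial failed and
    the search continues.

    Returns ``(best_params, trials)`` where ``trials`` is the full log.
    """
    space = space or HyperparameterSpace()
    rng = np.random.default_rng(seed)
    lo, hi = space.internal_bounds()
    dim = lo.size
    xs: list[np.ndarray] = []
    ys: list[float] = []
    trials: list[TrialResult] = []

    for t in range(n_trials):
        if len(ys) < n_startup:
            x = rng.uniform(lo, hi)
        else:
            order = np.argsort(ys)[::-1]  # descending: maximization
            n_good = max(1, int(math.ceil(gamma_quantile * len(ys))))
            good = np.array([xs[i] for i in order[:n_good]])
            rest = np.array([xs[i] for i in order[n_good:]])
            if rest.size == 0:
                rest = good
            x = np.empty(dim)
            for d in range(dim):
                span = hi[d] - lo[d]
                sig_g = max(span / max(len(good), 2), 1e-3 * span)
                sig_r = max(span / max(len(rest), 2), 1e-3 * span)
                centers = good[rng.integers(0, len(good), size=n_candidates), d]
                cands = np.clip(centers + sig_g * rng.standard_normal(n_candidates), lo[d], hi[d])
                score = _parzen_logpdf(cands, good[:, d], sig_g, lo[d], hi[d]) - _parzen_logpdf(
                    cands, rest[:, d], sig_r, lo[d], hi[d]
                )
                x[d] = cands[np.argmax(score)]
        params = space.inverse(x)
        try:
            y = float(objective(params))
        except Exception:
            trials.append(TrialResult(t, params, None, failed=True))
            continue
        xs.append(x)
        ys.append(y)
        trials.append(TrialResult(t, params, y))

    completed = [tr for tr in trials if not tr.failed]
    if not completed:
        raise RuntimeError("all trials failed")
    best = max(completed, key=lambda tr: tr.value)
    return best.params, trials


def trials_to_frame(trials) -> pd.DataFrame:
    rows = []
    for tr in trials:
        row = {"trial": tr.number, **tr.params, "objective": tr.value, "failed": tr.failed}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OVAT scans and the training objective


def training_objective(history: TrainingHistory, kind: str = "final-mean") -> float:
    """Scalar score of a training run.

    ``final-mean`` (default): mean cumulative reward over the final 20% of
    episodes.  ``best-c3``: best product concentration found.  ``auc``:
    area under the per-episode reward curve.
    """
    r = history.episode_returns
    if r.size == 0:
        raise ValueError("empty training history")
    if kind == "final-mean":
        tail = max(1, int(round(0.2 * r.size)))
        return float(np.mean(r[-tail:]))
    if kind == "best-c3":
        return float(history.best_c3)
    if kind == "auc":
        return float(np.trapezoid(r))
    raise ValueError(f"unknown objective kind {kind!r}")


def ovat_scan(
    param: str,
    values,
    base_config: TrainingConfig,
    env_factory,
    seeds=(0,),
) -> pd.DataFrame:
    """One-variable-at-a-time scan: train one agent per (value, seed) pair
    holding every other hyperparameter fixed.

    ``env_factory`` must return a fresh environment per run (reward-tracker
    state is per-training-run).  Returns one row per run with the episode
    returns and summary scores.
    """
    if not hasattr(base_config, param):
        raise ValueError(f"unknown hyperparameter {param!r}")
    rows = []
    for v in values:
        for s in seeds:
            cfg = TrainingConfig(**{**base_config.to_dict(), "adaptive_schedules": (), param: v, "seed": int(s)})
            hist = train(env_factory(), cfg)
            rows.append(
                {
                    "param": param,
                    "value": v,
                    "seed": s,
                    "objective": training_objective(hist),
                    "best_c3": hist.best_c3,
                    "final_ma10": float(hist.moving_average(10)[-1]),
                    "episode_returns": hist.episode_returns.tolist(),
                }
            )
    return pd.DataFrame(rows)
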