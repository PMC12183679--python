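"""Run configuration: schema-validated YAML loading and seeded RNG fan-out.

Unknown keys are rejected (typos fail loudly, at the offending path).  A
single global seed fans out to independent per-component streams via
``numpy.random.SeedSequence.spawn`` so the environment noise, network
initialization, buffer sampling and hyperparameter search can each be
re-seeded independently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .ddpg import TrainingConfig
from .reactor import KineticParameters, NumericsConfig, ReactorModel

__all__ = ["RunConfig", "load_config", "spawn_rngs", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReactorSection(_Strict):
    length: float = 0.15
    volume: float = 1.32e-6
    ua: float = 100.0
    dh_react: float = 160.0
    rho: float = 800.0
    cs1: float = 4.0
    cs2: float = 4.0
    ea: float = 21.57
    kref: float = 0.413
    tref: float = 298.15
    arrhenius_mode: str = "local-temperature"
    energy_coupling: bool = True

    def build(self) -> ReactorModel:
        return ReactorModel(
            length=self.length,
            volume=self.volume,
            ua=self.ua,
            dh_react=self.dh_react,
            rho=self.rho,
            cs1=self.cs1,
            cs2=self.cs2,
            kinetics=KineticParameters(ea=self.ea, kref=self.kref, tref=self.tref),
            arrhenius_mode=self.arrhenius_mode,
            energy_coupling=self.energy_coupling,
        )


class NumericsSection(_Strict):
    n_nodes: int = 400
    rtol: float = 1e-7
    atol: float = 1e-9

    def build(self) -> NumericsConfig:
        return NumericsConfig(n_nodes=self.n_nodes, rtol=self.rtol, atol=self.atol)


class AgentSection(_Strict):
    episodes: int = 100
    steps_per_episode: int = 10
    batch_size: int = 64
    buffer_capacity: int = 5000
    gamma: float = 0.961
    tau: float = 0.0004
    alpha_actor: float = 0.002
    alpha_critic: float = 0.00043
    sigma_e: float = 0.1019
    exploration_policy: str = "ou-noise"
    eps_min: float = 0.05
    lambda_decay: float = 0.01
    adaptive: list[str] = []  # hyperparameters under the linear-decay schedule

    def build(self, seed: int = 0) -> TrainingConfig:
        from .tuning import default_schedules

        cfg = TrainingConfig(
            episodes=self.episodes,
            steps_per_episode=self.steps_per_episode,
            batch_size=self.batch_size,
            buffer_capacity=self.buffer_capacity,
            gamma=self.gamma,
            tau=self.tau,
            alpha_actor=self.alpha_actor,
            alpha_critic=self.alpha_critic,
            sigma_e=self.sigma_e,
            exploration_policy=self.exploration_policy,
            eps_min=self.eps_min,
            lambda_decay=self.lambda_decay,
            seed=seed,
        )
        if self.adaptive:
            cfg.adaptive_schedules = default_schedules(cfg, tuple(self.adaptive))
        return cfg


class TuningSection(_Strict):
    n_trials: int = 15
    episodes_per_trial: int = 30
    objective: str = "final-mean"


class EstimateSection(_Strict):
    temps: list[float] = [288.0, 298.0, 313.0, 318.0]
    n_res_times: int = 12
    noise_level: float = 0.02
    er: float = 1.0


class BenchmarkSection(_Strict):
    methods: list[str] = ["nelder-mead", "snobfit", "ddpg"]
    nm_x0: list[float] = [0.66, 0.714, 280.55]
    nm_budget: int = 200
    snobfit_budget: int = 250


class GridSection(_Strict):
    resolution: list[int] = [20, 20, 20]


class SimulateSection(_Strict):
    res_t: float = 8.0
    er: float = 1.0
    temp: float = 330.0
    transient: bool = False


class RunConfig(_Strict):
    """The merged configuration tree for every subcommand."""

    seed: int = 0
    evaluator: str = "steady-state"
    reactor: ReactorSection = ReactorSection()
    numerics: NumericsSection = NumericsSection()
    agent: AgentSection = AgentSection()
    tuning: TuningSection = TuningSection()
    estimate: EstimateSection = EstimateSection()
    benchmark: BenchmarkSection = BenchmarkSection()
    grid: GridSection = GridSection()
    simulate: SimulateSection = SimulateSection()


def _set_dotted(tree: dict, key: str, value: str) -> None:
    parts = key.split(".")
    node = tree
    for p in parts[:-1]:
        node = node.setdefault(p, {})
    node[parts[-1]] = yaml.safe_load(value)


def load_config(path: str | Path | None = None, overrides=()) -> RunConfig:
    """Load a YAML config (or the defaults) and apply ``key=value`` dotted
    overrides.  Raises a schema error naming the offending key on any
    unknown or ill-typed entry."""
    tree: dict = {}
    if path is not None:
        with open(path) as fh:
            tree = yaml.safe_load(fh) or {}
    for ov in overrides:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} must look like section.key=value")
        k, v = ov.split("=", 1)
        _set_dotted(tree, k, v)
    try:
        return RunConfig(**tree)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"invalid config at {loc!r}: {first['msg']}") from err


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def spawn_rngs(seed: int, n: int = 4):
    """Independent RNG streams derived from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
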