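"""Deep deterministic policy gradient agent for reactor self-optimization.

The agent interacts with a :class:`FlowReactorEnv`: its state is the current
normalized reaction conditions plus the latest normalized outlet product
concentration, its actions are bounded increments of the three decision
variables (residence time, equivalent ratio, temperature), and its reward is
the hybrid threshold reward on the outlet imine concentration.

Training is episodic (default 100 episodes of 10 decision steps), off-policy
from a FIFO replay buffer, with soft-updated target networks and either
Ornstein-Uhlenbeck action noise or an epsilon-greedy policy for exploration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nets import Actor, Adam, Critic, hard_update, soft_update
from .reactor import (
    ConditionBounds,
    ReactionConditions,
    ReactorModel,
    analytic_isothermal_outlet,
    rate_constant,
    steady_state_outlet,
    simulate,
)
from .reward import RewardConfig, RewardTracker, compute_reward

__all__ = [
    "EnvState",
    "FlowReactorEnv",
    "ReplayBuffer",
    "OUNoise",
    "epsilon_schedule",
    "TrainingConfig",
    "DDPGAgent",
    "TrainingHistory",
    "train",
]

STATE_DIM = 4
ACTION_DIM = 3


def normalize_conditions(x: np.ndarray, bounds: ConditionBounds) -> np.ndarray:
    """Map raw conditions to [-1, 1] component-wise."""
    return np.clip(2.0 * (np.asarray(x) - bounds.lower) / bounds.span - 1.0, -1.0, 1.0)


@dataclass(frozen=True)
class EnvState:
    """Normalized agent state: conditions and latest outlet c3, all in [-1, 1]."""

    conditions: np.ndarray  # normalized (res_t, er, T)
    c3: float  # normalized outlet concentration

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.conditions, [self.c3]])


class FlowReactorEnv:
    """The reactor simulator wrapped as an episodic RL environment.

    Parameters
    ----------
    model : ReactorModel
        Physics of the environment.
    evaluator : {"steady-state", "analytic", "transient"}
        Outlet evaluation route.  "steady-state" integrates the axial ODEs
        (honors the energy balance); "analytic" uses the isothermal closed
        form (fast path, valid when the strong jacket pins T at the set
        point); "transient" runs the full method-of-lines simulation.
    action_scale : float
        Per-step maximum increment as a fraction of each variable's range.
    c3_scale : float
        Concentration (mol/L) mapped to +1 in the normalized state.
    """

    def __init__(
        self,
        model: ReactorModel | None = None,
        evaluator: str = "steady-state",
        reward_config: RewardConfig | None = None,
        action_scale: float = 0.2,
        c3_scale: float = 2.0,
    ):
        if evaluator not in ("steady-state", "analytic", "transient"):
            raise ValueError(f"unknown evaluator {evaluator!r}")
        self.model = model or ReactorModel()
        self.bounds = self.model.bounds
        self.evaluator = evaluator
        self.reward_config = reward_config or RewardConfig()
        self.tracker = RewardTracker()
        self.action_scale = action_scale
        self.c3_scale = c3_scale
        self.n_evaluations = 0
        self._cond: np.ndarray | None = None
        self._last_c3 = 0.0

    # -- outlet evaluation ------------------------------------------------
    def outlet_c3(self, x) -> float:
        """Steady-state outlet imine concentration at raw conditions ``x``
        (counts as one environment evaluation)."""
        x = np.asarray(x, dtype=float)
        cond = ReactionConditions.from_array(x)
        if self.evaluator == "analytic":
            k = rate_constant(cond.temp, self.model.kinetics)
            c3 = analytic_isothermal_outlet(cond, k, self.model.cs1, self.model.cs2)
        elif self.evaluator == "transient":
            c3 = simulate(cond, self.model).outlet_c3
        else:
            c3 = steady_state_outlet(cond, self.model)[2]
        self.n_evaluations += 1
        return float(c3)

    # -- episodic interface ----------------------------------------------
    def _observe(self) -> EnvState:
        return EnvState(
            conditions=normalize_conditions(self._cond, self.bounds),
            c3=float(np.clip(2.0 * self._last_c3 / self.c3_scale - 1.0, -1.0, 1.0)),
        )

    def reset(self, rng: np.random.Generator) -> EnvState:
        """Start an episode from uniformly random conditions within bounds."""
        self._cond = rng.uniform(self.bounds.lower, self.bounds.upper)
        self._last_c3 = self.outlet_c3(self._cond)
        self.tracker.update(self._last_c3)
        return self._observe()

    def step(self, action: np.ndarray):
        """Apply a bounded increment, evaluate the outlet, reward the agent.

        Returns ``(next_state, reward, c3, conditions)``.
        """
        if self._cond is None:
            raise RuntimeError("call reset() before step()")
        action = np.clip(np.asarray(action, dtype=float), -1.0, 1.0)
        delta = action * self.action_scale * self.bounds.span
        self._cond = self.bounds.clip(self._cond + delta)
        c3 = self.outlet_c3(self._cond)
        self._last_c3 = c3
        self.tracker.update(c3)
        r = compute_reward(c3, self.tracker, self.reward_config)
        return self._observe(), r, c3, self._cond.copy()


class ReplayBuffer:
    """Fixed-capacity FIFO experience store with uniform minibatch sampling
    (without replacement within a batch)."""

    def __init__(self, capacity: int = 5000, state_dim: int = STATE_DIM, action_dim: int = ACTION_DIM):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self.s = np.zeros((capacity, state_dim))
        self.a = np.zeros((capacity, action_dim))
        self.r = np.zeros(capacity)
        self.s2 = np.zeros((capacity, state_dim))
        self.done = np.zeros(capacity)
        self._next = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def add(self, s, a, r, s2, done) -> None:
        i = self._next
        self.s[i], self.a[i], self.r[i] = s, a, r
        self.s2[i], self.done[i] = s2, float(done)
        self._next = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        if batch_size > self._size:
            raise ValueError(f"cannot sample {batch_size} from buffer of size {self._size}")
        idx = rng.choice(self._size, size=batch_size, replace=False)
        return self.s[idx], self.a[idx], self.r[idx], self.s2[idx], self.done[idx]


@dataclass
class OUNoise:
    """Ornstein-Uhlenbeck exploration noise, independent per action dim:
    chi_t = chi_{t-1} + theta*(mu - chi_{t-1})*dt + sigma*sqrt(dt)*N(0, I).
    """

    dim: int = ACTION_DIM
    theta: float = 0.15
    mu: float = 0.0
    sigma: float = 0.1019
    dt: float = 1.0
    chi: np.ndarray | None = None

    def __post_init__(self):
        if self.chi is None:
            self.reset()

    def reset(self) -> None:
        self.chi = np.full(self.dim, self.mu, dtype=float)

    def step(self, rng: np.random.Generator) -> np.ndarray:
        self.chi = (
            self.chi
            + self.theta * (self.mu - self.chi) * self.dt
            + self.sigma * math.sqrt(self.dt) * rng.standard_normal(self.dim)
        )
        return self.chi.copy()


def epsilon_schedule(nt: int, eps_min: float, lam: float) -> float:
    """Exponentially decaying exploration probability
    eps = eps_min + (1 - eps_min) * exp(-lam * Nt)."""
    if nt < 0:
        raise ValueError("step count must be non-negative")
    return eps_min + (1.0 - eps_min) * math.exp(-lam * nt)


@dataclass
class TrainingConfig:
    """Agent and training-loop settings.

    Defaults are the Bayesian-optimization column of the tuned
    hyperparameters (alpha_critic 0.00043, alpha_actor 0.002, gamma 0.961,
    sigma_e 0.1019, tau 0.0004) with 100 episodes of 10 steps, batch 64 and
    a 5000-transition replay buffer.
    """

    episodes: int = 100
    steps_per_episode: int = 10
    batch_size: int = 64
    buffer_capacity: int = 5000
    gamma: float = 0.961
    tau: float = 0.0004
    alpha_actor: float = 0.002
    alpha_critic: float = 0.00043
    sigma_e: float = 0.1019
    exploration_policy: str = "ou-noise"  # or "epsilon-greedy"
    eps_min: float = 0.05
    lambda_decay: float = 0.01
    ou_theta: float = 0.15
    ou_mu: float = 0.0
    ou_dt: float = 1.0
    literal_soft_update: bool = False
    adaptive_schedules: tuple = ()  # objects with .applies_to and .value(ep, nt, n_total)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        for name in ("alpha_actor", "alpha_critic", "sigma_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exploration_policy not in ("ou-noise", "epsilon-greedy"):
            raise ValueError(f"unknown exploration policy {self.exploration_policy!r}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "adaptive_schedules"}
        d["adaptive_schedules"] = [getattr(s, "applies_to", "?") for s in self.adaptive_schedules]
        return d


class DDPGAgent:
    """Actor-critic pair with time-delayed target copies and Adam updates."""

    def __init__(self, config: TrainingConfig, rng: np.random.Generator,
                 state_dim: int = STATE_DIM, action_dim: int = ACTION_DIM):
        self.config = config
        self.actor = Actor(state_dim, action_dim, rng)
        self.critic = Critic(state_dim, action_dim, rng)
        self.actor_target = Actor(state_dim, action_dim, rng)
        self.critic_target = Critic(state_dim, action_dim, rng)
        hard_update(self.actor, self.actor_target)
        hard_update(self.critic, self.critic_target)
        self.actor_opt = Adam(self.actor.params(), lr=config.alpha_actor)
        self.critic_opt = Adam(self.critic.params(), lr=config.alpha_critic)

    def select_action(
        self,
        state: np.ndarray,
        noise: OUNoise | None = None,
        rng: np.random.Generator | None = None,
        epsilon: float | None = None,
    ) -> np.ndarray:
        """Policy output, optionally perturbed by OU noise or replaced by a
        uniform random action with probability ``epsilon``."""
        if epsilon is not None and rng is not None and rng.random() < epsilon:
            return rng.uniform(-1.0, 1.0, size=self.actor.action_dim)
        a = self.actor(np.asarray(state).reshape(1, -1))[0]
        if noise is not None:
            if rng is None:
                raise ValueError("OU noise requires an RNG")
            a = a + noise.step(rng)
        return np.clip(a, -1.0, 1.0)

    def critic_update(self, batch) -> float:
        """One TD step: targets y = r + gamma*Q'(s', mu'(s')) (r at terminal),
        minibatch MSE loss, single Adam step.  Returns the pre-step loss."""
        s, a, r, s2, done = batch
        if s.shape[0] == 0:
            raise ValueError("empty batch")
        a2 = self.actor_target(s2)
        q2 = self.critic_target(s2, a2)
        y = r + self.config.gamma * q2 * (1.0 - done)
        q = self.critic(s, a)
        err = q - y
        loss = float(np.mean(err**2))
        grads, _ = self.critic.backward(2.0 * err / err.size)
        self.critic_opt.step(grads)
        return loss

    def actor_update(self, batch) -> float:
        """Deterministic policy gradient ascent on mean Q(s, mu(s)).
        Returns the pre-step mean Q."""
        s = batch[0]
        a = self.actor(s)
        q = self.critic(s, a)
        _, grad_a = self.critic.backward(np.ones(s.shape[0]) / s.shape[0])
        self.actor(s)  # refresh forward cache on the current batch
        grads = self.actor.backward(-grad_a)  # ascend Q == descend -Q
        self.actor_opt.step(grads)
        return float(np.mean(q))

    def soft_update_targets(self) -> None:
        tau, lit = self.config.tau, self.config.literal_soft_update
        soft_update(self.actor, self.actor_target, tau, literal=lit)
        soft_update(self.critic, self.critic_target, tau, literal=lit)


@dataclass
class TrainingHistory:
    """Complete log of a training run: every environment evaluation, the
    per-episode returns, and the best conditions found."""

    records: pd.DataFrame  # episode, step, res_t, er, T_K, c3_M, reward, cum_reward, noise_mag
    episode_returns: np.ndarray
    best_conditions: ReactionConditions
    best_c3: float
    n_evaluations: int
    seed: int
    config: dict

    def moving_average(self, window: int = 10) -> np.ndarray:
        r = self.episode_returns
        if window > r.size:
            window = r.size
        return np.convolve(r, np.ones(window) / window, mode="valid")

    def summary(self) -> dict:
        return {
            "best_conditions": {
                "res_t": self.best_conditions.res_t,
                "er": self.best_conditions.er,
                "T": self.best_conditions.temp,
            },
            "best_c3": self.best_c3,
            "n_evaluations": self.n_evaluations,
            "episodes": int(self.episode_returns.size),
            "final_return": float(self.episode_returns[-1]),
            "seed": self.seed,
            "config_hash": hex(abs(hash(json.dumps(self.config, sort_keys=True, default=str)))),
        }

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def plot(self, ax=None):
        """Cumulative episodic reward with a 10-episode moving average."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.episode_returns, alpha=0.4, label="episode return")
        ma = self.moving_average(10)
        ax.plot(np.arange(ma.size) + (self.episode_returns.size - ma.size), ma,
                label="moving average (10)")
        ax.set_xlabel("episode")
        ax.set_ylabel("cumulative reward")
        ax.legend()
        return ax


def train(
    env: FlowReactorEnv,
    config: TrainingConfig | None = None,
    seed: int | None = None,
) -> TrainingHistory:
    """Run the episodic DDPG training loop against the reactor environment.

    Each environment step stores one transition and, once the buffer holds
    at least one batch, performs exactly one critic update, one actor
    update, and one soft target update.  Episode initial conditions are
    drawn uniformly within bounds; ``done`` is flagged only on the final
    step of an episode (no bootstrapping past the horizon).
    """
    config = config or TrainingConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    agent = DDPGAgent(config, rng)
    buffer = ReplayBuffer(config.buffer_capacity)
    noise = OUNoise(theta=config.ou_theta, mu=config.ou_mu, sigma=config.sigma_e, dt=config.ou_dt)
    use_ou = config.exploration_policy == "ou-noise"

    rows = []
    episode_returns = np.zeros(config.episodes)
    best_c3 = -np.inf
    best_cond = None
    global_step = 0
    n_total = config.steps_per_episode

    for ep in range(config.episodes):
        state = env.reset(rng).as_array()
        noise.reset()
        cum = 0.0
        for step in range(config.steps_per_episode):
            # adaptive hyperparameter schedules, evaluated on training progress
            for sched in config.adaptive_schedules:
                v = sched.value(ep, step, n_total)
                if sched.applies_to == "sigma_e":
                    noise.sigma = v
                elif sched.applies_to == "alpha_actor":
                    agent.actor_opt.lr = v
                elif sched.applies_to == "alpha_critic":
                    agent.critic_opt.lr = v

            if use_ou:
                action = agent.select_action(state, noise=noise, rng=rng)
                noise_mag = float(np.linalg.norm(noise.chi))
            else:
                eps = epsilon_schedule(global_step, config.eps_min, config.lambda_decay)
                action = agent.select_action(state, rng=rng, epsilon=eps)
                noise_mag = eps
            next_state_obj, r, c3, cond = env.step(action)
            next_state = next_state_obj.as_array()
            done = step == config.steps_per_episode - 1
            buffer.add(state, action, r, next_state, done)

            if len(buffer) >= config.batch_size:
                batch = buffer.sample(config.batch_size, rng)
                loss = agent.critic_update(batch)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite critic loss at episode {ep} step {step}: {loss}"
                    )
                agent.actor_update(batch)
                agent.soft_update_targets()

            cum += r
            if c3 > best_c3:
                best_c3, best_cond = c3, cond
            rows.append(
                (ep, step, cond[0], cond[1], cond[2], c3, r, cum, noise_mag)
            )
            state = next_state
            global_step += 1
        episode_returns[ep] = cum

    records = pd.DataFrame(
        rows,
        columns=["episode", "step", "res_t", "er", "T_K", "c3_M", "reward", "cum_reward", "noise_mag"],
    )
    return TrainingHistory(
        records=records,
        episode_returns=episode_returns,
        best_conditions=ReactionConditions.from_array(best_cond),
        best_c3=float(best_c3),
        n_evaluations=env.n_evaluations,
        seed=seed,
        config=config.to_dict(),
    )
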