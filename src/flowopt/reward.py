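"""Hybrid threshold reward on the outlet product concentration.

The reward normalizes the outlet imine concentration by the running extremes
experienced during training and adds a large bonus above 1.6 mol/L and a
penalty at or below 1.2 mol/L, steering the agent toward high-conversion
conditions while keeping a smooth gradient signal in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RewardConfig", "RewardTracker", "compute_reward", "discounted_return"]


@dataclass(frozen=True)
class RewardConfig:
    """Thresholds (mol/L) and offsets of the hybrid reward."""

    high_threshold: float = 1.6
    low_threshold: float = 1.2
    high_bonus: float = 100.0
    low_penalty: float = 15.0
    eps_guard: float = 1e-9

    def __post_init__(self) -> None:
        if self.low_threshold > self.high_threshold:
            raise ValueError("low threshold must not exceed high threshold")
        if self.eps_guard <= 0:
            raise ValueError("eps_guard must be positive")


@dataclass
class RewardTracker:
    """Running min/max of the product concentration seen during training.

    Extremes are global-running (accumulated over all episodes), matching
    the definition "experienced during training".
    """

    min_c3: float = field(default=np.inf)
    max_c3: float = field(default=-np.inf)

    def update(self, c3: float) -> None:
        if not np.isfinite(c3):
            raise ValueError(f"non-finite concentration {c3}")
        self.min_c3 = min(self.min_c3, c3)
        self.max_c3 = max(self.max_c3, c3)

    @property
    def initialized(self) -> bool:
        return np.isfinite(self.min_c3)


def compute_reward(
    c3: float, tracker: RewardTracker, config: RewardConfig | None = None
) -> float:
    """Hybrid reward for an outlet concentration ``c3`` (mol/L).

    The tracker must already include ``c3`` (call ``tracker.update(c3)``
    first), so the normalized value lies in [0, 1].  A degenerate tracker
    (max == min) yields normc = 0 via the epsilon guard rather than NaN.
    """
    config = config or RewardConfig()
    if not tracker.initialized:
        raise ValueError("reward tracker has no observations; call update() first")
    denom = max(tracker.max_c3 - tracker.min_c3, config.eps_guard)
    normc = (c3 - tracker.min_c3) / denom
    if c3 > config.high_threshold:
        return normc + config.high_bonus
    if c3 > config.low_threshold:
        return normc
    return normc - config.low_penalty


def discounted_return(rewards, gamma: float) -> float:
    """Discounted return G = sum_t gamma^t r_t for a finite reward sequence."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"discount factor must be in [0, 1], got {gamma}")
    rewards = np.asarray(rewards, dtype=float)
    return float(np.sum(rewards * gamma ** np.arange(rewards.size)))
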