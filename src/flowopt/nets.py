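"""Minimal dense neural networks for the actor-critic agent.

The actor and critic are small multilayer perceptrons (two hidden layers of
64 rectified-linear units).  Forward passes, backpropagation and the Adam
update are written directly on numpy arrays: the networks are small enough
that this is fast, fully deterministic under a seeded RNG, and free of
framework dependencies.

Conventions: batches are row-major ``(n, dim)`` float64 arrays; parameters
are stored as flat lists of arrays so target networks can be soft-updated
in place.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Actor", "Critic", "Adam", "soft_update", "hard_update"]


def _fan_in_init(rng: np.random.Generator, n_out: int, n_in: int, scale: float | None = None):
    """Uniform fan-in initialization; ``scale`` overrides the bound (used to
    keep the output layers near zero at the start of training)."""
    bound = scale if scale is not None else 1.0 / np.sqrt(n_in)
    w = rng.uniform(-bound, bound, size=(n_in, n_out))
    b = rng.uniform(-bound, bound, size=n_out)
    return w, b


def _relu(x):
    return np.maximum(x, 0.0)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Actor:
    """Deterministic policy network: state -> bounded action in [-1, 1]^d.

    Architecture: Dense(64)-ReLU, Dense(64)-ReLU, Dense(action_dim)-tanh.
    """

    def __init__(self, state_dim: int, action_dim: int, rng: np.random.Generator, hidden: int = 64):
        self.state_dim, self.action_dim = state_dim, action_dim
        self.w1, self.b1 = _fan_in_init(rng, hidden, state_dim)
        self.w2, self.b2 = _fan_in_init(rng, hidden, hidden)
        self.w3, self.b3 = _fan_in_init(rng, action_dim, hidden, scale=3e-3)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def forward(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        self._s = s
        self._h1 = _relu(s @ self.w1 + self.b1)
        self._h2 = _relu(self._h1 @ self.w2 + self.b2)
        self._a = np.tanh(self._h2 @ self.w3 + self.b3)
        return self._a

    __call__ = forward

    def backward(self, grad_a: np.ndarray):
        """Gradients of sum(grad_a * a) w.r.t. parameters (list matching
        :meth:`params`).  Must follow a :meth:`forward` call on the batch."""
        g3 = grad_a * (1.0 - self._a**2)  # through tanh
        gw3 = self._h2.T @ g3
        gb3 = g3.sum(axis=0)
        g2 = (g3 @ self.w3.T) * (self._h2 > 0)
        gw2 = self._h1.T @ g2
        gb2 = g2.sum(axis=0)
        g1 = (g2 @ self.w2.T) * (self._h1 > 0)
        gw1 = self._s.T @ g1
        gb1 = g1.sum(axis=0)
        return [gw1, gb1, gw2, gb2, gw3, gb3]


class Critic:
    """Action-value network Q(s, a).

    The state passes through a first hidden layer; the action is
    concatenated at the second hidden layer (the concatenation stage), and
    a linear head produces the scalar Q.
    """

    def __init__(self, state_dim: int, action_dim: int, rng: np.random.Generator, hidden: int = 64):
        self.state_dim, self.action_dim = state_dim, action_dim
        self.w1, self.b1 = _fan_in_init(rng, hidden, state_dim)
        self.w2, self.b2 = _fan_in_init(rng, hidden, hidden + action_dim)
        self.w3, self.b3 = _fan_in_init(rng, 1, hidden, scale=3e-3)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def forward(self, s: np.ndarray, a: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        a = np.atleast_2d(np.asarray(a, dtype=float))
        self._s, self._a = s, a
        self._h1 = _relu(s @ self.w1 + self.b1)
        self._cat = np.concatenate([self._h1, a], axis=1)
        self._h2 = _relu(self._cat @ self.w2 + self.b2)
        self._q = self._h2 @ self.w3 + self.b3
        return self._q[:, 0]

    __call__ = forward

    def backward(self, grad_q: np.ndarray):
        """Parameter gradients and the gradient w.r.t. the action input.

        Returns ``(param_grads, grad_action)`` for upstream signal
        ``grad_q`` of shape (n,) on the scalar outputs.
        """
        g3 = np.asarray(grad_q, dtype=float).reshape(-1, 1)
        gw3 = self._h2.T @ g3
        gb3 = g3.sum(axis=0)
        g2 = (g3 @ self.w3.T) * (self._h2 > 0)
        gw2 = self._cat.T @ g2
        gb2 = g2.sum(axis=0)
        gcat = g2 @ self.w2.T
        hidden = self._h1.shape[1]
        g1 = gcat[:, :hidden] * (self._h1 > 0)
        grad_action = gcat[:, hidden:]
        gw1 = self._s.T @ g1
        gb1 = g1.sum(axis=0)
        return [gw1, gb1, gw2, gb2, gw3, gb3], grad_action

    def action_gradient(self, s: np.ndarray, a: np.ndarray) -> np.ndarray:
        """dQ/da evaluated at (s, a), one row per sample."""
        self.forward(s, a)
        _, ga = self.backward(np.ones(self._q.shape[0]))
        return ga


def hard_update(source, target) -> None:
    """Copy source parameters into the target network."""
    for ps, pt in zip(source.params(), target.params()):
        pt[...] = ps


def soft_update(source, target, tau: float, literal: bool = False) -> None:
    """Polyak soft update of a target network.

    Default convention: theta' <- tau*theta + (1-tau)*theta', so larger tau
    makes the target track the main network faster (tau=1 copies it).  With
    ``literal=True`` the roles of tau and 1-tau are swapped.
    """
    if literal:
        tau = 1.0 - tau
    for ps, pt in zip(source.params(), target.params()):
        if ps.shape != pt.shape:
            raise ValueError(f"parameter shape mismatch {ps.shape} vs {pt.shape}")
        pt *= 1.0 - tau
        pt += tau * ps
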