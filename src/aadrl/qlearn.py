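"""Tabular Q-learning: Bellman value iteration and model-free TD updates.

Two complementary solvers live here.  ``value_iteration`` applies the
Bellman optimality update Q_{i+1}(s,a) = Σ_s' P(s'|s,a)[R(s,a) + γ max_a'
Q_i(s',a')] on an explicitly known MDP; it is the verifiable core of the
method.  For the decoding stream, where the transition model is implicit,
the standard model-free temporal-difference rule with learning rate α is
used with an ε-greedy behaviour policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .env import ACTIONS, AttentionEnv, Experience, reward_for
from .states import Codebook, StateSequence, quantize_sequence

__all__ = ["ExplicitMDP", "QTable", "QLConfig", "value_iteration",
           "td_update", "greedy_action", "epsilon_schedule", "run_ql_episode"]


@dataclass(frozen=True)
class ExplicitMDP:
    """Fully specified finite MDP: P[s, a, s'], R[s, a] and discount γ < 1."""

    P: np.ndarray
    R: np.ndarray
    gamma: float

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "R", R)
        if P.ndim != 3 or P.shape[0] != P.shape[2] or P.shape[:2] != R.shape:
            raise ValueError("P must be (S, A, S) and R must be (S, A)")
        if not (0 <= self.gamma < 1):
            raise ValueError("discount must satisfy 0 <= gamma < 1")
        if not np.allclose(P.sum(axis=2), 1.0, atol=1e-8):
            raise ValueError("every P[s, a] row must sum to 1")
        if np.any(P < -1e-12):
            raise ValueError("transition probabilities must be non-negative")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    @property
    def n_actions(self) -> int:
        return self.P.shape[1]


class QTable:
    """Sparse (state id, action) -> Q-value map with default 0."""

    def __init__(self, n_actions: int = 2):
        self.n_actions = n_actions
        self._q: dict = {}

    def get(self, s, a: int) -> float:
        return self._q.get((s, a), 0.0)

    def set(self, s, a: int, value: float) -> None:
        if not np.isfinite(value):
            raise FloatingPointError("Q-values must stay finite")
        self._q[(s, a)] = float(value)

    def values_for(self, s) -> np.ndarray:
        return np.array([self.get(s, a) for a in range(self.n_actions)])

    def __len__(self) -> int:
        return len(self._q)

    def to_dict(self) -> dict:
        return {f"{s}:{a}": v for (s, a), v in self._q.items()}

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "QTable":
        q = cls(n_actions=arr.shape[1])
        for s in range(arr.shape[0]):
            for a in range(arr.shape[1]):
                q.set(s, a, arr[s, a])
        return q


@dataclass(frozen=True)
class QLConfig:
    gamma: float = 0.9
    max_iterations: int = 50
    learning_rate: float = 0.1
    epsilon_start: float = 0.2
    epsilon_end: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.gamma < 1):
            raise ValueError("0 <= gamma < 1 required")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must lie in (0, 1]")


def value_iteration(mdp: ExplicitMDP, max_iterations: int = 50,
                    tol: float = 1e-10) -> QTable:
    """Iterate the Bellman optimality update to (near) fixed point.

    Stops when the max-norm change falls below ``tol`` or after
    ``max_iterations`` sweeps.  Successive sweeps contract, so the
    max-change sequence is non-increasing.
    """
    Q = np.zeros((mdp.n_states, mdp.n_actions))
    for _ in range(max_iterations):
        V = Q.max(axis=1)                      # max_a' Q_i(s', a')
        Q_new = mdp.R + mdp.gamma * np.einsum("sat,t->sa", mdp.P, V)
        delta = np.abs(Q_new - Q).max()
        Q = Q_new
        if delta < tol:
            break
    return QTable.from_array(Q)


def td_update(q: QTable, e: Experience, cfg: QLConfig) -> QTable:
    """Q(s,a) += α (r + γ max_a' Q(s',a') - Q(s,a)); terminal targets use r."""
    if e.s_next is None:
        target = e.r
    else:
        target = e.r + cfg.gamma * q.values_for(e.s_next).max()
    old = q.get(e.s, e.a)
    q.set(e.s, e.a, old + cfg.learning_rate * (target - old))
    return q


def greedy_action(q: QTable, s) -> int:
    """argmax_a Q(s, a); ties (including unseen states) resolve to LEFT."""
    return int(np.argmax(q.values_for(s)))


def epsilon_schedule(start: float, end: float, T: int) -> np.ndarray:
    """Linear exploration decay over an episode of T steps."""
    if T == 1:
        return np.array([end])
    return np.linspace(start, end, T)


def run_ql_episode(seq: StateSequence, codebook: Codebook,
                   cfg: QLConfig = QLConfig(), q: QTable | None = None):
    """Single online pass over the stream with ε-greedy TD learning.

    The trace records the greedy prediction at each decision time (and its
    ±1 reward); the executed ε-greedy action generates the experience the
    table learns from.
    """
    from .evaluation import DecisionTrace

    ids = quantize_sequence(seq, codebook)
    if q is None:
        q = QTable(n_actions=len(ACTIONS))
    rng = np.random.default_rng(cfg.seed)
    T = len(seq)
    eps = epsilon_schedule(cfg.epsilon_start, cfg.epsilon_end, T)
    preds = np.empty(T, dtype=np.int8)

    env = AttentionEnv(seq)
    env.reset()
    for t in range(T):
        s_id = ids[t]
        preds[t] = greedy_action(q, s_id)
        if rng.random() < eps[t]:
            a = int(rng.integers(len(ACTIONS)))
        else:
            a = int(preds[t])
        _, r, done = env.step(a)
        s_next = None if done else ids[t + 1]
        td_update(q, Experience(s_id, a, r, s_next), cfg)

    trace = DecisionTrace.from_predictions(seq.t_ms, seq.labels, preds, seq.hop_ms)
    return q, trace
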