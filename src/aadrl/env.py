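"""Sequential decision environment over a labeled state sequence.

The decoder's MDP: at each discrete step the agent observes the current
Markov state, issues an action in {left, right}, and receives reward +1 for
matching the true attended side and -1 otherwise.  Transitions are
action-independent — the next window of signal arrives regardless of the
decision — which makes the transition model degenerate but keeps the
reward/return machinery of Q-learning intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .labels import LEFT, RIGHT
from .states import MarkovState, StateSequence

__all__ = ["ACTIONS", "Experience", "AttentionEnv", "reward_for"]

ACTIONS = (LEFT, RIGHT)


def reward_for(action: int, true_label: int) -> int:
    """+1 for a correct attention call, -1 otherwise (no other values)."""
    return 1 if action == true_label else -1


@dataclass
class Experience:
    """One interaction tuple e_t = (S_t, A_t, R_t, S_{t+1}).

    ``s``/``s_next`` may be MarkovStates, raw feature vectors or discrete
    ids; ``s_next`` is None at the terminal step.  ``h``/``h_next`` carry the
    recurrent agent's hidden state at encounter time, when applicable.
    """

    s: object
    a: int
    r: int
    s_next: object | None
    h: object | None = None
    h_next: object | None = None

    def __post_init__(self):
        if self.r not in (-1, 1):
            raise ValueError("reward must be +1 or -1")
        if self.a not in ACTIONS:
            raise ValueError("action must be LEFT (0) or RIGHT (1)")


class AttentionEnv:
    """Walk a StateSequence step by step, scoring actions against true labels."""

    def __init__(self, seq: StateSequence):
        if len(seq) == 0:
            raise ValueError("empty state sequence")
        self.seq = seq
        self._cursor: Optional[int] = None
        self._done = False

    def reset(self) -> MarkovState:
        self._cursor = 0
        self._done = False
        return self.seq.state(0)

    @property
    def t(self) -> int:
        """Number of completed steps since reset."""
        if self._cursor is None:
            raise RuntimeError("environment not reset")
        return self._cursor

    @property
    def done(self) -> bool:
        return self._done

    def current_label(self) -> int:
        if self._cursor is None or self._done:
            raise RuntimeError("no current state")
        return int(self.seq.labels[self._cursor])

    def step(self, action: int):
        """Score ``action`` against the current state's label and advance.

        Returns (next_state | None, reward, done).
        """
        if self._cursor is None:
            raise RuntimeError("environment not reset")
        if self._done:
            raise RuntimeError("episode finished; call reset()")
        if action not in ACTIONS:
            raise ValueError("action must be LEFT (0) or RIGHT (1)")
        r = reward_for(action, int(self.seq.labels[self._cursor]))
        self._cursor += 1
        if self._cursor >= len(self.seq):
            self._done = True
            return None, r, True
        return self.seq.state(self._cursor), r, False
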