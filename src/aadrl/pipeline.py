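"""End-to-end runners tying states to learners.

A pipeline object exposes ``fit`` (online learning over one or more state
streams, weights carried across trials) and ``predict`` (frozen greedy
decisions on a new stream).  The online episode runners in the learner
modules remain the primary interface for single-trial dynamic decoding;
these wrappers exist for cross-trial protocols (the permutation test) and
for the command-line driver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dqlearn import DQLConfig, ReplayMemory, greedy_rollout, run_dql_episode
from .qlearn import QLConfig, QTable, greedy_action, run_ql_episode
from .rnn import RNNTrainConfig, rnn_predict, run_rnn_episode
from .states import Codebook, StateSequence, fit_codebook, quantize_sequence

__all__ = ["DQLPipeline", "QLPipeline", "RNNPipeline", "ConstantPipeline",
           "make_pipeline"]


@dataclass
class DQLPipeline:
    """Deep Q-learning decoder with a DNN or RNN agent."""

    agent_kind: str = "rnn"
    cfg: DQLConfig = DQLConfig()

    def fit(self, seqs: list):
        net = None
        mem = ReplayMemory(self.cfg.capacity)
        for i, seq in enumerate(seqs):
            cfg = replace(self.cfg, seed=self.cfg.seed + i)
            net, _ = run_dql_episode(seq, self.agent_kind, cfg, net=net, mem=mem)
        return net

    def predict(self, net, seq: StateSequence) -> np.ndarray:
        return greedy_rollout(net, seq)

    def run(self, seq: StateSequence):
        return run_dql_episode(seq, self.agent_kind, self.cfg)


@dataclass
class QLPipeline:
    """Tabular Q-learning decoder on quantized states."""

    cfg: QLConfig = QLConfig()
    n_bins: int = 3
    calibration_fraction: float = 0.2

    def fit(self, seqs: list):
        codebook = fit_codebook(seqs[0], self.n_bins, self.calibration_fraction)
        q = QTable()
        for i, seq in enumerate(seqs):
            cfg = replace(self.cfg, seed=self.cfg.seed + i)
            q, _ = run_ql_episode(seq, codebook, cfg, q=q)
        return codebook, q

    def predict(self, model, seq: StateSequence) -> np.ndarray:
        codebook, q = model
        ids = quantize_sequence(seq, codebook)
        return np.array([greedy_action(q, s) for s in ids], dtype=np.int8)

    def run(self, seq: StateSequence):
        codebook = fit_codebook(seq, self.n_bins, self.calibration_fraction)
        return run_ql_episode(seq, codebook, self.cfg)


@dataclass
class RNNPipeline:
    """Online recurrent classifier."""

    cfg: RNNTrainConfig = RNNTrainConfig()

    def fit(self, seqs: list):
        params = None
        for seq in seqs:
            params, _ = run_rnn_episode(seq, self.cfg, params=params)
        return params

    def predict(self, params, seq: StateSequence) -> np.ndarray:
        preds = np.empty(len(seq), dtype=np.int8)
        h = params.zero_hidden()
        for t in range(len(seq)):
            preds[t], h = rnn_predict(params, seq.features[t], h)
        return preds

    def run(self, seq: StateSequence):
        return run_rnn_episode(seq, self.cfg)


@dataclass
class ConstantPipeline:
    """Degenerate baseline that always answers one side; used to validate
    the permutation machinery (its permuted accuracy equals the permuted
    label base rate exactly)."""

    side: int = 0

    def fit(self, seqs: list):
        return self.side

    def predict(self, side, seq: StateSequence) -> np.ndarray:
        return np.full(len(seq), side, dtype=np.int8)


def make_pipeline(kind: str, **kwargs):
    """Factory for CLI-style learner names: rnn, ql, dql-dnn, dql-rnn."""
    if kind == "rnn":
        return RNNPipeline(**kwargs)
    if kind == "ql":
        return QLPipeline(**kwargs)
    if kind == "dql-dnn":
        return DQLPipeline(agent_kind="dnn", **kwargs)
    if kind == "dql-rnn":
        return DQLPipeline(agent_kind="rnn", **kwargs)
    raise ValueError(f"unknown learner kind: {kind}")
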