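"""Decoding statistics: accuracy, cumulative-accuracy curves, detection
delay, label-permutation null and the switching-attention report.

The cumulative accuracy at step t is the fraction of correct decisions among
steps 0..t; detection delay is the earliest time from which the curve stays
within an ε-band of its final value.  The permutation test re-runs the
decoding pipeline with whole-trial attended-side labels randomly reassigned
across trials, training on one fold and scoring frozen on the held-out fold
("cross folding"), which collapses any valid pipeline to chance (50% in a
two-class problem).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import LEFT
from .states import StateSequence

__all__ = ["DecisionTrace", "ConfusionCounts", "DelayResult",
           "PermutationResult", "accuracy", "cumulative_accuracy",
           "detection_delay", "permutation_test", "switching_report"]


@dataclass(frozen=True)
class DecisionTrace:
    """Per-step decisions of one episode; rewards are ±1 and agree with the
    predicted/true label match by construction."""

    t_ms: np.ndarray
    true: np.ndarray
    pred: np.ndarray
    rewards: np.ndarray
    hop_ms: float

    def __post_init__(self):
        n = self.t_ms.size
        if not (self.true.size == self.pred.size == self.rewards.size == n):
            raise ValueError("trace arrays must share one length")
        expected = np.where(self.pred == self.true, 1, -1)
        if not np.array_equal(np.asarray(self.rewards), expected):
            raise ValueError("rewards inconsistent with label agreement")

    @classmethod
    def from_predictions(cls, t_ms, true, pred, hop_ms) -> "DecisionTrace":
        true = np.asarray(true, dtype=np.int8)
        pred = np.asarray(pred, dtype=np.int8)
        rewards = np.where(pred == true, 1, -1).astype(np.int8)
        return cls(np.asarray(t_ms, dtype=float), true, pred, rewards, float(hop_ms))

    def __len__(self) -> int:
        return self.t_ms.size

    @property
    def final_accuracy(self) -> float:
        return float(np.mean(self.pred == self.true))


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts with 'left' as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_trace(cls, trace: DecisionTrace) -> "ConfusionCounts":
        pos = trace.true == LEFT
        pred_pos = trace.pred == LEFT
        return cls(TP=int(np.sum(pos & pred_pos)),
                   TN=int(np.sum(~pos & ~pred_pos)),
                   FP=int(np.sum(~pos & pred_pos)),
                   FN=int(np.sum(pos & ~pred_pos)))


def accuracy(counts: ConfusionCounts) -> float:
    """ACC = (TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("no decisions to score")
    return (counts.TP + counts.TN) / counts.total


def cumulative_accuracy(trace: DecisionTrace) -> np.ndarray:
    """curve[t] = fraction of correct decisions among steps 0..t."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    correct = (trace.pred == trace.true).astype(float)
    return np.cumsum(correct) / np.arange(1, len(trace) + 1)


@dataclass(frozen=True)
class DelayResult:
    delay_ms: float
    stabilized: bool


def detection_delay(curve: np.ndarray, hop_ms: float,
                    epsilon: float = 0.02) -> DelayResult:
    """Time for the cumulative decision to reach a stable state.

    delay = t* · hop_ms with t* the smallest index such that every later
    curve value stays within ``epsilon`` of the final value.  If only the
    final point qualifies, the delay is (T-1)·hop_ms with the
    ``stabilized`` flag cleared.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    final = curve[-1]
    inside = np.abs(curve - final) <= epsilon
    # suffix_ok[t] <=> curve stays in the band from t onward; the final point
    # always qualifies, so t_star is well defined
    suffix_ok = np.flip(np.cumprod(np.flip(inside))).astype(bool)
    t_star = int(np.argmax(suffix_ok))
    if curve.size > 1 and t_star == curve.size - 1:
        return DelayResult((curve.size - 1) * hop_ms, False)
    return DelayResult(t_star * hop_ms, True)


@dataclass(frozen=True)
class PermutationResult:
    mean: float
    sd: float
    accuracies: np.ndarray
    n_perm: int


def permutation_test(pipeline, seqs: list, n_perm: int = 100, seed: int = 0,
                     n_folds: int = 2, scheme: str = "flip") -> PermutationResult:
    """Label-permutation null of the full decoding pipeline.

    Per repetition, whole-trial attended-side labels are randomly relabeled,
    the pipeline is fit on each training fold with the relabeled data and
    its frozen policy scored on the held-out trials against the relabeled
    test labels ("cross folding"); the pooled accuracy of the repetition is
    recorded.

    Relabeling schemes:
      ``flip``      each trial independently keeps or mirrors (left<->right)
                    its label sequence with probability 1/2.  Train and test
                    folds are then independent, so the null is centered at
                    exactly 50% for any decoder.
      ``exchange``  the multiset of label sequences is permuted across
                    trials (exact class balance).  With few trials this
                    classical scheme couples the folds negatively and its
                    null center falls below chance.

    ``pipeline`` must provide ``fit(list[StateSequence]) -> model`` and
    ``predict(model, StateSequence) -> label array``.
    """
    if len(seqs) < 2:
        raise ValueError("permutation requires at least two trials")
    if scheme not in ("flip", "exchange"):
        raise ValueError("scheme must be 'flip' or 'exchange'")
    lengths = {len(s) for s in seqs}
    if scheme == "exchange" and len(lengths) != 1:
        raise ValueError("trials must share one length for label exchange")
    n = len(seqs)
    labels_pool = [s.labels.copy() for s in seqs]
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)

    for rep in range(n_perm):
        if scheme == "flip":
            flips = rng.random(n) < 0.5
            permuted = [1 - labels_pool[i] if flips[i] else labels_pool[i]
                        for i in range(n)]
        else:
            assign = rng.permutation(n)
            permuted = [labels_pool[assign[i]] for i in range(n)]
        order = rng.permutation(n)
        correct = 0
        total = 0
        for fold in np.array_split(order, n_folds):
            test_idx = set(int(i) for i in fold)
            train = [seqs[i].with_labels(permuted[i])
                     for i in range(n) if i not in test_idx]
            if not train:
                continue
            model = pipeline.fit(train)
            for i in test_idx:
                pred = np.asarray(pipeline.predict(model, seqs[i]))
                correct += int(np.sum(pred == permuted[i]))
                total += pred.size
        accs[rep] = correct / total
    return PermutationResult(float(accs.mean()), float(accs.std(ddof=1)),
                             accs, n_perm)


def switching_report(traces_by_segment: dict, epsilon: float = 0.02) -> pd.DataFrame:
    """Per segment-length condition: mean ± sd of final accuracy and delay.

    ``traces_by_segment`` maps segment duration in seconds to the list of
    DecisionTraces obtained under that switching schedule.
    """
    rows = []
    for seg_s in sorted(traces_by_segment):
        traces = traces_by_segment[seg_s]
        if not traces:
            raise ValueError(f"no traces for segment length {seg_s}")
        accs = np.array([t.final_accuracy for t in traces])
        delays = np.array([
            detection_delay(cumulative_accuracy(t), t.hop_ms, epsilon).delay_ms
            for t in traces])
        rows.append({
            "segment_s": seg_s,
            "n_runs": len(traces),
            "acc_mean": accs.mean(),
            "acc_sd": accs.std(ddof=1) if len(accs) > 1 else 0.0,
            "delay_ms_mean": delays.mean(),
            "delay_ms_sd": delays.std(ddof=1) if len(delays) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
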