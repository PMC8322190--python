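"""From-scratch stacked recurrent classifier with truncated BPTT.

The recurrence per layer l is  h^l_t = tanh(W_hh[l] h^l_{t-1} + W_sh[l] x^l_t)
with x^1_t the state vector and x^l_t = h^{l-1}_t for deeper layers; the
output is linear, o_t = W_ho h^L_t.  There are no bias terms — the model is
exactly the weight set {W_sh, W_hh, W_ho}.  Training minimizes the squared
error against one-hot targets over a short trailing window (truncated
backpropagation through time), iterating gradient steps at each time step
until the window loss falls below a stop threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LEFT
from .states import StateSequence

__all__ = ["RNNParams", "RNNTrainConfig", "init_rnn", "rnn_step", "rnn_predict",
           "rnn_forward_window", "rnn_window_gradients", "rnn_fit_step",
           "run_rnn_episode"]


@dataclass
class RNNParams:
    W_sh: list            # per layer: (H, in_dim) — in_dim = D for layer 0, else H
    W_hh: list            # per layer: (H, H)
    W_ho: np.ndarray      # (2, H)

    @property
    def n_layers(self) -> int:
        return len(self.W_sh)

    @property
    def n_hidden(self) -> int:
        return self.W_hh[0].shape[0]

    def copy(self) -> "RNNParams":
        return RNNParams([w.copy() for w in self.W_sh],
                         [w.copy() for w in self.W_hh],
                         self.W_ho.copy())

    def zero_hidden(self) -> list:
        return [np.zeros(self.n_hidden) for _ in range(self.n_layers)]


@dataclass(frozen=True)
class RNNTrainConfig:
    """Training hyperparameters; architecture defaults follow the decoder's
    reference configuration (10 stacked layers of 100 tanh units)."""

    n_layers: int = 10
    n_hidden: int = 100
    stop_threshold: float = 1e-3
    bptt_steps: int = 3
    learning_rate: float = 0.01
    max_inner_iters: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")
        if self.bptt_steps < 1:
            raise ValueError("bptt_steps must be >= 1")
        if self.n_layers < 1 or self.n_hidden < 1:
            raise ValueError("architecture sizes must be positive")


def init_rnn(cfg: RNNTrainConfig, input_dim: int, output_dim: int = 2) -> RNNParams:
    """Seeded small random weights, scaled by 1/sqrt(fan_in)."""
    if input_dim < 1:
        raise ValueError("input_dim must be positive")
    rng = np.random.default_rng(cfg.seed)

    def w(shape):
        return rng.uniform(-1, 1, shape) / np.sqrt(shape[1])

    W_sh, W_hh = [], []
    for l in range(cfg.n_layers):
        in_dim = input_dim if l == 0 else cfg.n_hidden
        W_sh.append(w((cfg.n_hidden, in_dim)))
        W_hh.append(w((cfg.n_hidden, cfg.n_hidden)))
    return RNNParams(W_sh, W_hh, w((output_dim, cfg.n_hidden)))


def rnn_step(params: RNNParams, s_t: np.ndarray, h_prev: list):
    """One forward step; returns (o_hat, new hidden states per layer)."""
    s_t = np.asarray(s_t, dtype=float)
    if s_t.size != params.W_sh[0].shape[1]:
        raise ValueError("state dimension does not match W_sh")
    x = s_t
    h_new = []
    for l in range(params.n_layers):
        h = np.tanh(params.W_hh[l] @ h_prev[l] + params.W_sh[l] @ x)
        h_new.append(h)
        x = h
    return params.W_ho @ h_new[-1], h_new


def rnn_predict(params: RNNParams, s_t: np.ndarray, h_prev: list):
    """Predicted side = argmax of the linear output; ties go to LEFT."""
    o, h = rnn_step(params, s_t, h_prev)
    return int(np.argmax(o)), h


def rnn_forward_window(params: RNNParams, X: np.ndarray, h0: list):
    """Forward over a (k, D) window from initial hidden states ``h0``.

    Returns (outputs (k, 2), hidden trajectory H[t][l]).
    """
    k = X.shape[0]
    H = []
    O = np.empty((k, params.W_ho.shape[0]))
    h_prev = h0
    for t in range(k):
        O[t], h_prev = rnn_step(params, X[t], h_prev)
        H.append(h_prev)
    return O, H


def _one_hot(labels: np.ndarray, n: int = 2) -> np.ndarray:
    Y = np.zeros((labels.size, n))
    Y[np.arange(labels.size), labels] = 1.0
    return Y


def rnn_window_gradients(params: RNNParams, X: np.ndarray, labels: np.ndarray,
                         h0: list):
    """Loss and exact gradients of the window loss L = Σ_t ||o_t - y_t||².

    Backpropagation through time over the window, treating ``h0`` as a
    constant (truncation boundary).
    """
    O, H = rnn_forward_window(params, X, h0)
    Y = _one_hot(np.asarray(labels))
    R = O - Y
    loss = float(np.sum(R * R))

    L = params.n_layers
    k = X.shape[0]
    gW_sh = [np.zeros_like(w) for w in params.W_sh]
    gW_hh = [np.zeros_like(w) for w in params.W_hh]
    gW_ho = np.zeros_like(params.W_ho)
    future_da = [np.zeros(params.n_hidden) for _ in range(L)]

    for t in range(k - 1, -1, -1):
        do = 2.0 * R[t]
        gW_ho += np.outer(do, H[t][L - 1])
        da_above = None
        new_future = [None] * L
        for l in range(L - 1, -1, -1):
            dh = params.W_hh[l].T @ future_da[l]
            if l == L - 1:
                dh = dh + params.W_ho.T @ do
            if da_above is not None:
                dh = dh + params.W_sh[l + 1].T @ da_above
            da = dh * (1.0 - H[t][l] ** 2)
            h_before = H[t - 1][l] if t > 0 else h0[l]
            gW_hh[l] += np.outer(da, h_before)
            x = X[t] if l == 0 else H[t][l - 1]
            gW_sh[l] += np.outer(da, x)
            new_future[l] = da
            da_above = da
        future_da = new_future

    return loss, gW_sh, gW_hh, gW_ho


def rnn_fit_step(params: RNNParams, recent_states: np.ndarray,
                 recent_labels: np.ndarray, cfg: RNNTrainConfig,
                 h0: list | None = None):
    """Iterate gradient steps on the trailing window until the loss drops
    below the stop threshold (or the safety cap is hit).

    The loss is checked before each update, so a window already fit below
    threshold leaves the parameters untouched.  Returns (params', final loss).
    """
    X = np.atleast_2d(np.asarray(recent_states, dtype=float))
    labels = np.asarray(recent_labels)
    out = params.copy()
    if h0 is None:
        h0 = out.zero_hidden()
    loss = None
    for _ in range(cfg.max_inner_iters):
        loss, gW_sh, gW_hh, gW_ho = rnn_window_gradients(out, X, labels, h0)
        if not np.isfinite(loss):
            raise FloatingPointError("RNN training loss diverged")
        if loss < cfg.stop_threshold:
            return out, loss
        lr = cfg.learning_rate
        for l in range(out.n_layers):
            out.W_sh[l] -= lr * gW_sh[l]
            out.W_hh[l] -= lr * gW_hh[l]
        out.W_ho -= lr * gW_ho
    loss, *_ = rnn_window_gradients(out, X, labels, h0)
    return out, float(loss)


def run_rnn_episode(seq: StateSequence, cfg: RNNTrainConfig,
                    params: RNNParams | None = None):
    """Online protocol: predict each state before its label is used to train.

    A trailing buffer of ``bptt_steps`` states is maintained together with
    the hidden state at the buffer's entry (advanced with the current
    weights as states leave the truncation window).  Returns the trained
    parameters and a DecisionTrace.
    """
    from .evaluation import DecisionTrace

    if params is None:
        params = init_rnn(cfg, seq.n_features)
    h_enter = params.zero_hidden()
    buf_states: list[np.ndarray] = []
    buf_labels: list[int] = []
    preds = np.empty(len(seq), dtype=np.int8)

    for t in range(len(seq)):
        s_t = seq.features[t]
        # prediction BEFORE the label is revealed: replay the buffer from the
        # truncation boundary and take the output at the new state
        h = h_enter
        for s_past in buf_states:
            _, h = rnn_step(params, s_past, h)
        preds[t], _ = rnn_predict(params, s_t, h)

        buf_states.append(s_t)
        buf_labels.append(int(seq.labels[t]))
        if len(buf_states) > cfg.bptt_steps:
            _, h_enter = rnn_step(params, buf_states.pop(0), h_enter)
            buf_labels.pop(0)
        params, _ = rnn_fit_step(params, np.array(buf_states),
                                 np.array(buf_labels), cfg, h0=h_enter)

    trace = DecisionTrace.from_predictions(seq.t_ms, seq.labels, preds, seq.hop_ms)
    return params, trace
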