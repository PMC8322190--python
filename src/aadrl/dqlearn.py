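"""Deep Q-learning with experience replay and a frozen target network.

Two Q-network agents approximate the action-value function: a feedforward
network with sigmoid hidden layers and a recurrent network with tanh hidden
layers (one-step truncated backpropagation; each stored experience carries
the hidden state it was encountered with).  Updates minimize the standard
temporal-difference loss

    L_i(θ_i) = E[(y - Q(S_t, A_t; θ_i))²],
    y = R_t                                   (terminal)
    y = R_t + γ max_a' Q(S_{t+1}, a'; θ_{i-1})  (otherwise)

where θ_{i-1} are the weights of a periodically synchronized target copy.
Networks are bias-free (pure weight matrices), matching the package's RNN
classifier.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .env import ACTIONS, AttentionEnv, Experience
from .states import StateSequence

__all__ = ["ReplayMemory", "QNetworkDNN", "QNetworkRNN", "DQLConfig",
           "remember", "sample_batch", "q_forward", "dql_update",
           "run_dql_episode", "init_q_network", "greedy_rollout"]


class ReplayMemory:
    """Bounded FIFO store of experiences; eviction is strictly oldest-first."""

    def __init__(self, capacity: int = 2000):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._buf: deque = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._buf)

    def __iter__(self):
        return iter(self._buf)

    def __getitem__(self, i):
        return self._buf[i]


def remember(mem: ReplayMemory, e: Experience) -> ReplayMemory:
    mem._buf.append(e)
    return mem


def sample_batch(mem: ReplayMemory, batch_size: int, seed=None) -> list:
    """Uniform sample without replacement; ``seed`` may be an int or a Generator."""
    if len(mem) < batch_size:
        raise LookupError("not enough experiences to sample a batch")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(mem), size=batch_size, replace=False)
    return [mem[int(i)] for i in idx]


# ---------------------------------------------------------------------------
# Q-networks

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class QNetworkDNN:
    """Feedforward Q-network: sigmoid hidden layers, linear 2-unit output.

    Unlike the package's recurrent classifier (whose printed equations are
    pure weight products), the Q-networks carry standard bias terms.
    """

    Ws: list     # per layer (out_dim, in_dim); last layer is the linear output
    bs: list     # per layer (out_dim,)

    def copy(self) -> "QNetworkDNN":
        return QNetworkDNN([w.copy() for w in self.Ws],
                           [b.copy() for b in self.bs])

    def forward_batch(self, X: np.ndarray):
        A = np.atleast_2d(X)
        acts = [A]
        for w, b in zip(self.Ws[:-1], self.bs[:-1]):
            A = _sigmoid(A @ w.T + b)
            acts.append(A)
        return A @ self.Ws[-1].T + self.bs[-1], acts

    def zero_hidden(self):
        return None


@dataclass
class QNetworkRNN:
    """Recurrent Q-network: stacked tanh layers, linear output, bptt of 1."""

    W_sh: list
    W_hh: list
    W_ho: np.ndarray
    bs: list              # per recurrent layer (H,)
    b_o: np.ndarray       # (2,)

    @property
    def n_layers(self) -> int:
        return len(self.W_sh)

    @property
    def n_hidden(self) -> int:
        return self.W_hh[0].shape[0]

    def copy(self) -> "QNetworkRNN":
        return QNetworkRNN([w.copy() for w in self.W_sh],
                           [w.copy() for w in self.W_hh], self.W_ho.copy(),
                           [b.copy() for b in self.bs], self.b_o.copy())

    def zero_hidden(self):
        return [np.zeros(self.n_hidden) for _ in range(self.n_layers)]

    def forward_batch(self, X: np.ndarray, H_prev: list):
        """X: (B, D); H_prev: per layer (B, H).  Returns (Q (B,2), hiddens)."""
        A = np.atleast_2d(X)
        hs = []
        for l in range(self.n_layers):
            A = np.tanh(H_prev[l] @ self.W_hh[l].T + A @ self.W_sh[l].T
                        + self.bs[l])
            hs.append(A)
        return hs[-1] @ self.W_ho.T + self.b_o, hs


@dataclass(frozen=True)
class DQLConfig:
    """Deep Q-learning hyperparameters.

    The default discount is 0: the stream's transitions are action
    independent, so the greedy policy is invariant to the discount and the
    myopic target (expected immediate reward) gives stationary, stable
    learning; any discount in [0, 1) may be configured.  The replay capacity
    of 100 steps (12.5 s at the default hop) keeps the decoder able to track
    attention switches at the few-second time scale.
    """

    batch_size: int = 32
    gamma: float = 0.0
    learning_rate: float = 0.1
    target_sync_every: int = 50
    epsilon_start: float = 0.2
    epsilon_end: float = 0.01
    capacity: int = 100
    n_hidden: int = 100
    n_hidden_layers: int = 3     # hidden (DNN) or recurrent (RNN agent) layers
    stop_threshold: float = 1e-2  # inner-loop loss cap per update
    max_inner_iters: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0 <= self.gamma < 1):
            raise ValueError("0 <= gamma < 1 required")


def init_q_network(agent_kind: str, input_dim: int, cfg: DQLConfig,
                   output_dim: int = 2):
    """Seeded 1/sqrt(fan_in)-scaled uniform init for either agent kind."""
    rng = np.random.default_rng(cfg.seed)

    def w(shape):
        return rng.uniform(-1, 1, shape) / np.sqrt(shape[1])

    if agent_kind == "dnn":
        dims = [input_dim] + [cfg.n_hidden] * cfg.n_hidden_layers + [output_dim]
        return QNetworkDNN([w((dims[i + 1], dims[i])) for i in range(len(dims) - 1)],
                           [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)])
    if agent_kind == "rnn":
        W_sh, W_hh = [], []
        for l in range(cfg.n_hidden_layers):
            in_dim = input_dim if l == 0 else cfg.n_hidden
            W_sh.append(w((cfg.n_hidden, in_dim)))
            W_hh.append(w((cfg.n_hidden, cfg.n_hidden)))
        return QNetworkRNN(W_sh, W_hh, w((output_dim, cfg.n_hidden)),
                           [np.zeros(cfg.n_hidden) for _ in range(cfg.n_hidden_layers)],
                           np.zeros(output_dim))
    raise ValueError("agent_kind must be 'dnn' or 'rnn'")


def q_forward(net, s: np.ndarray, h_prev=None):
    """Action values for one state.  The recurrent agent also returns its
    updated hidden state; the feedforward agent returns None in its place."""
    s = np.asarray(s, dtype=float)
    if isinstance(net, QNetworkRNN):
        if h_prev is None:
            h_prev = net.zero_hidden()
        H_prev = [h[None, :] for h in h_prev]
        Q, hs = net.forward_batch(s[None, :], H_prev)
        return Q[0], [h[0] for h in hs]
    Q, _ = net.forward_batch(s[None, :])
    return Q[0], None


def _batch_arrays(net, batch: list):
    X = np.stack([np.asarray(e.s, dtype=float) for e in batch])
    a_idx = np.array([e.a for e in batch])
    r = np.array([e.r for e in batch], dtype=float)
    if isinstance(net, QNetworkRNN):
        H_prev = [np.stack([
            (e.h[l] if e.h is not None else np.zeros(net.n_hidden))
            for e in batch]) for l in range(net.n_layers)]
        return X, a_idx, r, H_prev
    return X, a_idx, r, None


def _targets(target_net, batch: list, gamma: float) -> np.ndarray:
    y = np.array([e.r for e in batch], dtype=float)
    live = [j for j, e in enumerate(batch) if e.s_next is not None]
    if live:
        Xn = np.stack([np.asarray(batch[j].s_next, dtype=float) for j in live])
        if isinstance(target_net, QNetworkRNN):
            Hn = [np.stack([
                (batch[j].h_next[l] if batch[j].h_next is not None
                 else np.zeros(target_net.n_hidden)) for j in live])
                for l in range(target_net.n_layers)]
            Qn, _ = target_net.forward_batch(Xn, Hn)
        else:
            Qn, _ = target_net.forward_batch(Xn)
        y[live] += gamma * Qn.max(axis=1)
    return y


def _loss_and_grads_dnn(net: QNetworkDNN, X, a_idx, y):
    Q, acts = net.forward_batch(X)
    B = X.shape[0]
    qa = Q[np.arange(B), a_idx]
    resid = qa - y
    loss = float(np.mean(resid ** 2))
    dOut = np.zeros_like(Q)
    dOut[np.arange(B), a_idx] = 2.0 * resid / B
    grads = [None] * len(net.Ws)
    gbs = [None] * len(net.Ws)
    grads[-1] = dOut.T @ acts[-1]
    gbs[-1] = dOut.sum(axis=0)
    dA = dOut @ net.Ws[-1]
    for l in range(len(net.Ws) - 2, -1, -1):
        dZ = dA * acts[l + 1] * (1.0 - acts[l + 1])
        grads[l] = dZ.T @ acts[l]
        gbs[l] = dZ.sum(axis=0)
        if l > 0:
            dA = dZ @ net.Ws[l]
    return loss, grads, gbs


def _loss_and_grads_rnn(net: QNetworkRNN, X, a_idx, y, H_prev):
    Q, hs = net.forward_batch(X, H_prev)
    B = X.shape[0]
    qa = Q[np.arange(B), a_idx]
    resid = qa - y
    loss = float(np.mean(resid ** 2))
    dOut = np.zeros_like(Q)
    dOut[np.arange(B), a_idx] = 2.0 * resid / B
    gW_ho = dOut.T @ hs[-1]
    gb_o = dOut.sum(axis=0)
    gW_sh = [None] * net.n_layers
    gW_hh = [None] * net.n_layers
    gbs = [None] * net.n_layers
    dH = dOut @ net.W_ho
    for l in range(net.n_layers - 1, -1, -1):
        dA = dH * (1.0 - hs[l] ** 2)
        gW_hh[l] = dA.T @ H_prev[l]
        x = X if l == 0 else hs[l - 1]
        gW_sh[l] = dA.T @ x
        gbs[l] = dA.sum(axis=0)
        if l > 0:
            dH = dA @ net.W_sh[l]
    return loss, (gW_sh, gW_hh, gW_ho, gbs, gb_o)


def dql_update(net, target_net, batch: list, cfg: DQLConfig):
    """TD update of the online network against frozen targets.

    Gradient descent is repeated on the sampled batch until the loss falls
    below the agent's stop threshold or the safety cap is hit (the targets
    stay fixed within the loop — they come from the frozen copy).  The loss
    is checked before each step, so a batch already fit below threshold
    leaves the weights untouched.  Returns (net, final loss).
    """
    y = _targets(target_net, batch, cfg.gamma)
    X, a_idx, r, H_prev = _batch_arrays(net, batch)
    lr = cfg.learning_rate
    recurrent = isinstance(net, QNetworkRNN)

    loss = None
    for _ in range(cfg.max_inner_iters):
        if recurrent:
            loss, (gW_sh, gW_hh, gW_ho, gbs, gb_o) = _loss_and_grads_rnn(
                net, X, a_idx, y, H_prev)
        else:
            loss, grads, gbs = _loss_and_grads_dnn(net, X, a_idx, y)
        if not np.isfinite(loss):
            raise FloatingPointError("DQL loss diverged")
        if loss < cfg.stop_threshold:
            return net, loss
        if recurrent:
            for l in range(net.n_layers):
                net.W_sh[l] -= lr * gW_sh[l]
                net.W_hh[l] -= lr * gW_hh[l]
                net.bs[l] -= lr * gbs[l]
            net.W_ho -= lr * gW_ho
            net.b_o -= lr * gb_o
        else:
            for l in range(len(net.Ws)):
                net.Ws[l] -= lr * grads[l]
                net.bs[l] -= lr * gbs[l]
    if recurrent:
        loss, _ = _loss_and_grads_rnn(net, X, a_idx, y, H_prev)
    else:
        loss, _, _ = _loss_and_grads_dnn(net, X, a_idx, y)
    return net, float(loss)


def run_dql_episode(seq: StateSequence, agent_kind: str = "rnn",
                    cfg: DQLConfig = DQLConfig(), net=None, mem=None):
    """Online DQL pass over a state stream.

    Per step: greedy prediction is recorded (with its ±1 reward), an
    ε-greedy action is executed and stored in replay, and once the memory
    holds a batch the online network takes a TD update; the target network
    is synchronized every ``target_sync_every`` updates.
    Returns (net, DecisionTrace).
    """
    from .evaluation import DecisionTrace

    if agent_kind not in ("dnn", "rnn"):
        raise ValueError("agent_kind must be 'dnn' or 'rnn'")
    if net is None:
        net = init_q_network(agent_kind, seq.n_features, cfg)
    if mem is None:
        mem = ReplayMemory(cfg.capacity)
    target_net = net.copy()
    rng = np.random.default_rng(cfg.seed)
    T = len(seq)
    eps = np.linspace(cfg.epsilon_start, cfg.epsilon_end, max(T, 2))[:T]
    preds = np.empty(T, dtype=np.int8)

    env = AttentionEnv(seq)
    env.reset()
    h = net.zero_hidden()
    n_updates = 0
    for t in range(T):
        s_t = seq.features[t]
        q, h_next = q_forward(net, s_t, h)
        preds[t] = int(np.argmax(q))
        if rng.random() < eps[t]:
            a = int(rng.integers(len(ACTIONS)))
        else:
            a = int(preds[t])
        _, r, done = env.step(a)
        s_next = None if done else seq.features[t + 1]
        remember(mem, Experience(s_t, a, r, s_next, h=h, h_next=h_next))
        h = h_next

        if len(mem) >= cfg.batch_size:
            batch = sample_batch(mem, cfg.batch_size, rng)
            net, _ = dql_update(net, target_net, batch, cfg)
            n_updates += 1
            if n_updates % cfg.target_sync_every == 0:
                target_net = net.copy()

    trace = DecisionTrace.from_predictions(seq.t_ms, seq.labels, preds, seq.hop_ms)
    return net, trace


def greedy_rollout(net, seq: StateSequence) -> np.ndarray:
    """Frozen-policy predictions over a stream (no exploration, no updates)."""
    preds = np.empty(len(seq), dtype=np.int8)
    h = net.zero_hidden()
    for t in range(len(seq)):
        q, h = q_forward(net, seq.features[t], h)
        preds[t] = int(np.argmax(q))
    return preds
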