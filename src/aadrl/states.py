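"""Markovian state construction from (EEG, left envelope, right envelope).

A probabilistic state-space view of the decoding problem needs a state S_t
that summarizes the observation window at time t.  The state used here is
the classical sufficient-statistic family of envelope-tracking decoders:
Pearson correlations, at a small set of neural lags, between each ear's
envelope and group-averaged EEG within a sliding window, plus per-group log
energies.  Windows are placed so every lagged envelope window lies inside
the trial, hence the first state ends ``window + max_lag`` samples in.

Downstream learners see only the state vectors and labels, never raw EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import Trial

__all__ = ["StateConfig", "MarkovState", "StateSequence", "Codebook",
           "build_states", "fit_codebook", "quantize_state", "quantize_sequence"]

_EPS_VAR = 1e-18


@dataclass(frozen=True)
class StateConfig:
    window_s: float = 1.0
    hop_samples: int = 8                      # 125 ms at 64 Hz
    lags_ms: tuple = (0.0, 62.5, 125.0, 187.5, 250.0)
    n_channel_groups: int = 8
    zscore: bool = True
    projection_dim: int | None = None
    projection_seed: int = 0

    def __post_init__(self):
        if self.window_s <= 0 or self.hop_samples < 1:
            raise ValueError("window_s must be > 0 and hop_samples >= 1")
        if self.n_channel_groups < 1:
            raise ValueError("need at least one channel group")
        if any(l < 0 for l in self.lags_ms):
            raise ValueError("lags must be non-negative")


@dataclass(frozen=True)
class MarkovState:
    features: np.ndarray
    t_index: int
    t_ms: float


@dataclass(frozen=True)
class StateSequence:
    """Time-ordered state vectors with per-state attended-side labels."""

    features: np.ndarray     # (T, D)
    labels: np.ndarray       # (T,) int8
    t_ms: np.ndarray         # window-end times, ms
    hop_ms: float

    def __post_init__(self):
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features and labels must align")
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int8))

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def state(self, i: int) -> MarkovState:
        return MarkovState(self.features[i], i, float(self.t_ms[i]))

    def with_labels(self, labels: np.ndarray) -> "StateSequence":
        return replace(self, labels=np.asarray(labels, dtype=np.int8))


def _cumsums(x: np.ndarray):
    out = np.empty(x.size + 1)
    out[0] = 0.0
    np.cumsum(x, out=out[1:])
    return out


def build_states(trial: Trial, cfg: StateConfig = StateConfig()) -> StateSequence:
    """Slide a window over the trial and emit one feature vector per position.

    Feature layout (fixed order):
      [left-envelope block: group g=0..G-1 x lag] then the same right-envelope
      block, then per-group log window energies.  Swapping the ear envelopes
      swaps the two correlation blocks exactly.
    """
    fs = trial.fs
    W = int(round(cfg.window_s * fs))
    lags = [int(round(l * fs / 1000.0)) for l in cfg.lags_ms]
    lag_max = max(lags)
    n = trial.n_samples
    if n < W + lag_max:
        raise ValueError("trial shorter than window plus maximum lag")
    if max(lags) >= W:
        raise ValueError("lags must lie within the window")

    starts = np.arange(lag_max, n - W + 1, cfg.hop_samples)
    T = starts.size
    G = cfg.n_channel_groups
    groups = np.array_split(np.arange(trial.n_channels), G)
    geeg = np.stack([trial.eeg[g].mean(axis=0) for g in groups])  # (G, n)

    n_lags = len(lags)
    D = 2 * G * n_lags + G
    F = np.empty((T, D))
    col = 0
    for env in (trial.left_env.samples, trial.right_env.samples):
        for g in range(G):
            for lag in lags:
                F[:, col] = _corr_pairs(env, geeg[g], starts, W, lag)
                col += 1
    for g in range(G):
        Sqq = _cumsums(geeg[g] * geeg[g])
        F[:, col] = np.log((Sqq[starts + W] - Sqq[starts]) / W + 1e-12)
        col += 1

    if cfg.zscore:
        F = _running_zscore(F, n_pair=G * n_lags)
    if cfg.projection_dim is not None:
        rng = np.random.default_rng(cfg.projection_seed)
        P = rng.standard_normal((D, cfg.projection_dim)) / np.sqrt(D)
        F = F @ P

    ends = starts + W
    t_ms = ends * 1000.0 / fs
    labels = trial.labels[ends - 1]     # label at the window's final sample
    return StateSequence(F, labels, t_ms, cfg.hop_samples * 1000.0 / fs)


def _corr_pairs(env, geeg, starts, W, lag):
    """corr(env[s-lag : s-lag+W], eeg[s : s+W]) for each window start s."""
    Sx, Sxx = _cumsums(env), _cumsums(env * env)
    Sy, Syy = _cumsums(geeg), _cumsums(geeg * geeg)
    prod = env[: env.size - lag] * geeg[lag:] if lag else env * geeg
    Sxy = _cumsums(prod)
    es = starts - lag            # envelope window start (always >= 0 here)
    sx = Sx[es + W] - Sx[es]
    sy = Sy[starts + W] - Sy[starts]
    cross = Sxy[es + W] - Sxy[es]
    cov = cross - sx * sy / W
    vx = np.maximum((Sxx[es + W] - Sxx[es]) - sx * sx / W, 0.0)
    vy = np.maximum((Syy[starts + W] - Syy[starts]) - sy * sy / W, 0.0)
    denom = np.sqrt(vx * vy)
    ok = (vx > _EPS_VAR * np.maximum(1.0, Sxx[es + W] - Sxx[es])) & \
         (vy > _EPS_VAR * np.maximum(1.0, Syy[starts + W] - Syy[starts]))
    out = np.zeros_like(cov)
    np.divide(cov, denom, where=ok & (denom > 0), out=out)
    return out


def _running_zscore(F: np.ndarray, n_pair: int = 0) -> np.ndarray:
    """Causal z-scoring: each state is standardized by statistics of states 0..t.

    The first ``2 * n_pair`` columns are the left/right correlation blocks;
    each left column and its right twin share pooled statistics, so the
    attended-side contrast (their mean difference) survives normalization.
    A purely per-dimension z-score would subtract exactly the quantity that
    separates the classes on a constant-attention trial.  Remaining columns
    are standardized per dimension.
    """
    T = F.shape[0]
    n = np.arange(1, T + 1)[:, None].astype(float)
    mu = np.cumsum(F, axis=0) / n
    var = np.maximum(np.cumsum(F * F, axis=0) / n - mu * mu, 0.0)
    if n_pair:
        left, right = slice(0, n_pair), slice(n_pair, 2 * n_pair)
        mu_pool = 0.5 * (mu[:, left] + mu[:, right])
        # pooled second moment -> pooled variance about the pooled mean
        m2 = 0.5 * ((var[:, left] + mu[:, left] ** 2)
                    + (var[:, right] + mu[:, right] ** 2))
        var_pool = np.maximum(m2 - mu_pool ** 2, 0.0)
        mu = mu.copy()
        var = var.copy()
        mu[:, left] = mu[:, right] = mu_pool
        var[:, left] = var[:, right] = var_pool
    sd = np.sqrt(var)
    out = np.zeros_like(F)
    np.divide(F - mu, sd, where=sd > 1e-8, out=out)
    return out


# ---------------------------------------------------------------------------
# discretization for tabular Q-learning

@dataclass(frozen=True)
class Codebook:
    """Per-dimension quantile bin edges (B bins => B-1 internal edges)."""

    edges: np.ndarray            # (D, B-1)
    n_bins: int
    calibration_fraction: float = 0.2

    @property
    def n_dims(self) -> int:
        return self.edges.shape[0]


def fit_codebook(seq: StateSequence, B: int = 3,
                 calibration_fraction: float = 0.2) -> Codebook:
    """Quantile edges estimated on the first ``calibration_fraction`` of states."""
    if B < 2:
        raise ValueError("need at least two bins")
    if not (0 < calibration_fraction <= 1):
        raise ValueError("calibration_fraction must lie in (0, 1]")
    n_cal = max(1, int(round(calibration_fraction * len(seq))))
    cal = seq.features[:n_cal]
    qs = np.arange(1, B) / B
    edges = np.quantile(cal, qs, axis=0).T   # (D, B-1)
    return Codebook(edges, B, calibration_fraction)


def quantize_state(state, codebook: Codebook) -> int:
    """Deterministic mixed-radix id of the per-dimension bin tuple.

    The first dimension is the most significant digit: bins (1, 2) with B=3
    map to 1*3 + 2 = 5.  Ids are exact Python ints (they can exceed 64 bits
    for high-dimensional states).
    """
    vec = state.features if isinstance(state, MarkovState) else np.asarray(state)
    if vec.size != codebook.n_dims:
        raise ValueError("state dimension does not match codebook")
    idx = 0
    B = codebook.n_bins
    for d in range(vec.size):
        b = int(np.searchsorted(codebook.edges[d], vec[d], side="right"))
        idx = idx * B + b
    return idx


def quantize_sequence(seq: StateSequence, codebook: Codebook) -> list[int]:
    if seq.n_features != codebook.n_dims:
        raise ValueError("sequence dimension does not match codebook")
    B = codebook.n_bins
    bins = np.empty((len(seq), codebook.n_dims), dtype=np.int64)
    for d in range(codebook.n_dims):
        bins[:, d] = np.searchsorted(codebook.edges[d], seq.features[:, d],
                                     side="right")
    ids = []
    for row in bins:
        idx = 0
        for b in row:
            idx = idx * B + int(b)
        ids.append(idx)
    return ids
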