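"""Synthetic dichotic-listening trials with a known attended stream.

This module emulates the statistical structure that an EEG attention decoder
relies on: each EEG channel contains a lagged, filtered copy of the attended
speech envelope at higher gain than the unattended envelope, plus noise.  It
is a declared stand-in for real cortical recordings — channel kernels are
seeded random FIR filters, not physiological temporal response functions —
but it preserves the property the decoder exploits (envelope tracking biased
toward the attended ear) and supports attention-switching schedules.

All generators are deterministic given their seed arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .labels import LEFT, SIDE_NAMES, labels_to_chars, other_side, parse_side

__all__ = [
    "Envelope",
    "SwitchSchedule",
    "Trial",
    "GeneratorConfig",
    "make_envelope",
    "make_switch_schedule",
    "make_random_schedule",
    "synthesize_trial",
    "labels_from_schedule",
    "schedule_from_labels",
    "write_trial",
    "read_trial",
]


@dataclass(frozen=True)
class Envelope:
    """Non-negative amplitude-modulation signal sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 1:
            raise ValueError("envelope must be one-dimensional")
        if self.samples.size and self.samples.min() < 0:
            raise ValueError("envelope values must be non-negative")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class SwitchSchedule:
    """Ordered (duration_s, attended side) segments covering ``total_s`` seconds."""

    segments: tuple
    total_s: float

    def __post_init__(self):
        segs = tuple((float(d), parse_side(s)) for d, s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if any(d <= 0 for d, _ in segs):
            raise ValueError("segment durations must be positive")
        if not np.isclose(sum(d for d, _ in segs), self.total_s):
            raise ValueError("segment durations must sum to total_s")

    @property
    def n_switches(self) -> int:
        sides = [s for _, s in self.segments]
        return int(np.sum(np.diff(sides) != 0))


@dataclass
class Trial:
    """A dichotic trial: EEG matrix, the two ear envelopes and per-sample labels."""

    eeg: np.ndarray            # (n_channels, n_samples)
    left_env: Envelope
    right_env: Envelope
    labels: np.ndarray         # int8 per-sample side
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n = self.eeg.shape[1]
        if not (len(self.left_env) == len(self.right_env) == self.labels.size == n):
            raise ValueError("eeg, envelopes and labels must share n_samples")
        if self.eeg.shape[0] < 1:
            raise ValueError("need at least one EEG channel")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]


@dataclass(frozen=True)
class GeneratorConfig:
    """Forward model parameters for the stimulus→EEG stand-in.

    ``attended_gain``/``unattended_gain`` scale the convolved attended and
    unattended envelopes in every channel; ``noise_sd`` is the standard
    deviation of additive white Gaussian sensor noise.  ``kernel_lags_ms``
    is the support of the per-channel random FIR kernel.
    """

    n_channels: int = 128
    fs: float = 128.0
    kernel_lags_ms: tuple = (0.0, 250.0)
    attended_gain: float = 1.0
    unattended_gain: float = 0.2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.attended_gain < 0 or self.unattended_gain < 0:
            raise ValueError("gains must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.kernel_lags_ms
        if hi < lo:
            raise ValueError("kernel lag support must be non-empty")


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 4) -> np.ndarray:
    cutoff = min(cutoff_hz, 0.45 * fs)
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(x.size - 1, 3 * (2 * sos.shape[0] + 1))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


_SMOOTH_CUTOFF_HZ = 6.0   # second-stage smoothing after rectification: a
_SMOOTH_ORDER = 8         # steep filter keeps >99% of power below 8 Hz


def make_envelope(duration_s: float, fs: float, seed: int) -> Envelope:
    """Random speech-envelope-like signal: rectified, 8 Hz low-passed noise.

    Gaussian noise is low-passed at 8 Hz, full-wave rectified, low-passed
    again to remove rectification harmonics, and clipped at zero.  The result
    is non-negative with nearly all spectral power below 8 Hz, mimicking the
    slow amplitude modulations of running speech.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be non-negative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs))
    if n == 0:
        return Envelope(np.empty(0), fs)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if n < 32:  # too short for stable zero-phase filtering
        return Envelope(np.abs(white), fs)
    slow = _lowpass(white, fs, 8.0)
    env = _lowpass(np.abs(slow), fs, _SMOOTH_CUTOFF_HZ, order=_SMOOTH_ORDER)
    # remove the (rare, tiny) negative undershoot of the smoother as a DC
    # shift, which keeps the spectrum concentrated at low frequencies
    return Envelope(env - min(env.min(), 0.0), fs)


def make_switch_schedule(segment_s: float, total_s: float, start_side) -> SwitchSchedule:
    """Alternating attended-side schedule of equal segments (e.g. 12 × 5 s in 60 s)."""
    if segment_s <= 0 or total_s <= 0:
        raise ValueError("durations must be positive")
    ratio = total_s / segment_s
    n_seg = int(round(ratio))
    if abs(ratio - n_seg) > 1e-9 or n_seg < 1:
        raise ValueError("segment_s must divide total_s")
    side = parse_side(start_side)
    segments = []
    for _ in range(n_seg):
        segments.append((segment_s, side))
        side = other_side(side)
    return SwitchSchedule(tuple(segments), total_s)


def make_random_schedule(segment_s: float, total_s: float, seed: int,
                         p_left: float = 0.5) -> SwitchSchedule:
    """Schedule with an independent random side per segment.

    With segments at or below the decoder's hop this yields per-decision
    labels with no temporal structure — the appropriate null condition for
    an online learner that receives reward feedback (an alternating or
    slowly switching schedule is still partially predictable from the reward
    stream alone).
    """
    if segment_s <= 0 or total_s <= 0:
        raise ValueError("durations must be positive")
    ratio = total_s / segment_s
    n_seg = int(round(ratio))
    if abs(ratio - n_seg) > 1e-9 or n_seg < 1:
        raise ValueError("segment_s must divide total_s")
    rng = np.random.default_rng(seed)
    sides = np.where(rng.random(n_seg) < p_left, LEFT, 1 - LEFT)
    return SwitchSchedule(tuple((segment_s, int(s)) for s in sides), total_s)


def labels_from_schedule(schedule: SwitchSchedule, fs: float) -> np.ndarray:
    """Expand a schedule to a per-sample int8 label array at rate ``fs``."""
    n_total = int(round(schedule.total_s * fs))
    labels = np.empty(n_total, dtype=np.int8)
    t = 0.0
    prev = 0
    for dur, side in schedule.segments:
        t += dur
        end = int(round(t * fs))
        labels[prev:end] = side
        prev = end
    return labels


def schedule_from_labels(labels: np.ndarray, fs: float) -> SwitchSchedule:
    """Re-segment a per-sample label array into a schedule (inverse of expansion)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    segments = tuple(
        ((e - s) / fs, int(labels[s])) for s, e in zip(bounds[:-1], bounds[1:])
    )
    return SwitchSchedule(segments, labels.size / fs)


def _channel_kernels(cfg: GeneratorConfig, seed: int) -> np.ndarray:
    """Seeded unit-norm random FIR kernels, one per channel, on the lag support."""
    lo, hi = cfg.kernel_lags_ms
    n_lag = int(round((hi - lo) * cfg.fs / 1000.0)) + 1
    rng = np.random.default_rng(seed)
    k = rng.standard_normal((cfg.n_channels, n_lag))
    k /= np.linalg.norm(k, axis=1, keepdims=True)
    return k


def synthesize_trial(schedule: SwitchSchedule, cfg: GeneratorConfig,
                     seed: int | None = None) -> Trial:
    """Generate a Trial whose EEG tracks the scheduled attended envelope.

    Per channel c:  eeg_c = attended_gain * (k_c ⊛ env_att)
                          + unattended_gain * (k_c ⊛ env_unatt) + noise,
    where env_att follows the schedule sample by sample and k_c is the
    channel's seeded FIR kernel (causal, truncated to the trial length).
    """
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    s_left, s_right, s_noise = (int(s) & 0x7FFFFFFF for s in ss.generate_state(3))
    # channel kernels play the role of the listener's stimulus->EEG forward
    # model: stable across trials of one subject, hence seeded by the config
    # seed, not the per-trial seed
    s_kern = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0]) & 0x7FFFFFFF
    left = make_envelope(schedule.total_s, cfg.fs, s_left)
    right = make_envelope(schedule.total_s, cfg.fs, s_right)
    labels = labels_from_schedule(schedule, cfg.fs)
    n = labels.size

    att = np.where(labels == LEFT, left.samples, right.samples)
    unatt = np.where(labels == LEFT, right.samples, left.samples)
    kernels = _channel_kernels(cfg, s_kern)

    eeg = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        eeg[c] = (
            cfg.attended_gain * np.convolve(att, kernels[c])[:n]
            + cfg.unattended_gain * np.convolve(unatt, kernels[c])[:n]
        )
    if cfg.noise_sd > 0:
        noise_rng = np.random.default_rng(s_noise)
        eeg += cfg.noise_sd * noise_rng.standard_normal(eeg.shape)

    meta = {
        "seed": int(seed),
        "generator": asdict(cfg),
        "schedule": [[d, SIDE_NAMES[s]] for d, s in schedule.segments],
    }
    return Trial(eeg, left, right, labels, cfg.fs, meta)


# ---------------------------------------------------------------------------
# on-disk trial container: delimited text + JSON meta (plain-text formats)

def write_trial(trial: Trial, outdir, stem: str = "trial") -> dict:
    """Write a trial as TSV matrices, one-char-per-line labels and JSON meta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "eeg": outdir / f"{stem}_eeg.tsv",
        "left_env": outdir / f"{stem}_left_env.tsv",
        "right_env": outdir / f"{stem}_right_env.tsv",
        "labels": outdir / f"{stem}_labels.txt",
        "meta": outdir / f"{stem}_meta.json",
    }
    np.savetxt(paths["eeg"], trial.eeg, delimiter="\t")
    np.savetxt(paths["left_env"], trial.left_env.samples, delimiter="\t")
    np.savetxt(paths["right_env"], trial.right_env.samples, delimiter="\t")
    paths["labels"].write_text("\n".join(labels_to_chars(trial.labels)) + "\n")
    meta = dict(trial.meta)
    meta["fs"] = trial.fs
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def read_trial(outdir, stem: str = "trial") -> Trial:
    outdir = Path(outdir)
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    fs = float(meta.pop("fs"))
    eeg = np.loadtxt(outdir / f"{stem}_eeg.tsv", delimiter="\t", ndmin=2)
    left = np.loadtxt(outdir / f"{stem}_left_env.tsv", delimiter="\t")
    right = np.loadtxt(outdir / f"{stem}_right_env.tsv", delimiter="\t")
    chars = (outdir / f"{stem}_labels.txt").read_text().split()
    from .labels import chars_to_labels

    return Trial(eeg, Envelope(left, fs), Envelope(right, fs),
                 chars_to_labels(chars), fs, meta)
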