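"""EEG/stimulus preprocessing: band-pass filtering, resampling, envelopes.

EEG is band-pass filtered to 2-30 Hz (the band carrying envelope-tracking
cortical activity) with a zero-phase forward-backward Butterworth filter,
then everything is brought to a common 64 Hz rate.  Audio envelopes are the
magnitude of the analytic signal, low-passed at 8 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .synthetic import Envelope, Trial

__all__ = ["FilterSpec", "bandpass", "resample_to", "resample_labels",
           "audio_envelope", "prepare_trial"]

TARGET_FS = 64.0


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase band-pass specification (order is per filtering direction)."""

    low_hz: float = 2.0
    high_hz: float = 30.0
    order: int = 4
    notch_hz: float | None = None   # optional mains notch, off by default

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def bandpass(eeg: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis."""
    if fs <= 2 * spec.high_hz:
        raise ValueError("band edge exceeds Nyquist: need fs > 2*high_hz")
    eeg = np.asarray(eeg, dtype=float)
    sos = signal.butter(spec.order, (spec.low_hz, spec.high_hz),
                        btype="band", fs=fs, output="sos")
    padlen = min(eeg.shape[-1] - 1, 3 * (2 * sos.shape[0] + 1))
    out = signal.sosfiltfilt(sos, eeg, axis=-1, padlen=padlen)
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, Q=30.0, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling along the last axis; identity at equal rates."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_out == fs_in:
        return np.array(x, dtype=float, copy=True)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(x, dtype=float),
                                frac.numerator, frac.denominator, axis=-1)


def resample_labels(labels: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Nearest-sample label resampling (labels are categorical, not filtered)."""
    labels = np.asarray(labels)
    if fs_out == fs_in:
        return labels.copy()
    n_out = int(round(labels.size * fs_out / fs_in))
    idx = np.minimum((np.arange(n_out) * fs_in / fs_out).astype(int), labels.size - 1)
    return labels[idx]


def audio_envelope(waveform: np.ndarray, fs: float, cutoff_hz: float = 8.0) -> Envelope:
    """Slow amplitude envelope: |analytic signal|, low-passed, clipped at 0."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if fs <= 2 * cutoff_hz:
        raise ValueError("need fs > 2*cutoff_hz")
    mag = np.abs(signal.hilbert(waveform))
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = min(waveform.size - 1, 3 * (2 * sos.shape[0] + 1))
    env = signal.sosfiltfilt(sos, mag, padlen=padlen)
    return Envelope(np.clip(env, 0.0, None), fs)


def prepare_trial(trial: Trial, spec: FilterSpec = FilterSpec(),
                  fs_out: float = TARGET_FS) -> Trial:
    """Band-pass the EEG and bring EEG, envelopes and labels to ``fs_out``.

    Envelopes are resampled with anti-aliasing and re-clipped at zero (the
    polyphase filter can produce small negative ripples).
    """
    eeg = bandpass(trial.eeg, trial.fs, spec)
    eeg = resample_to(eeg, trial.fs, fs_out)
    left = np.clip(resample_to(trial.left_env.samples, trial.fs, fs_out), 0, None)
    right = np.clip(resample_to(trial.right_env.samples, trial.fs, fs_out), 0, None)
    labels = resample_labels(trial.labels, trial.fs, fs_out)
    n = min(eeg.shape[1], left.size, right.size, labels.size)
    meta = dict(trial.meta)
    meta["preprocess"] = {"low_hz": spec.low_hz, "high_hz": spec.high_hz,
                          "order": spec.order, "notch_hz": spec.notch_hz,
                          "fs_out": fs_out}
    return Trial(eeg[:, :n], Envelope(left[:n], fs_out), Envelope(right[:n], fs_out),
                 labels[:n], fs_out, meta)
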