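"""File-format helpers: delimited text, WAV audio, EDF EEG, traces.

Delimited text (channels × samples) is the canonical EEG container; WAV is
read/written through scipy and EDF through mne when it is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .evaluation import DecisionTrace
from .labels import SIDE_CHARS

__all__ = ["read_eeg_text", "write_eeg_text", "read_wav", "write_wav",
           "read_eeg_edf", "write_trace", "write_curve"]


def read_eeg_text(path, delimiter="\t") -> np.ndarray:
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)


def write_eeg_text(path, eeg: np.ndarray, delimiter="\t") -> None:
    np.savetxt(path, np.atleast_2d(eeg), delimiter=delimiter)


def read_wav(path):
    """Returns (samples as float64 in [-1, 1] for integer PCM, fs)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)


def write_wav(path, samples: np.ndarray, fs: float) -> None:
    wavfile.write(path, int(round(fs)), np.asarray(samples, dtype=np.float32))


def read_eeg_edf(path):
    """Load an EDF recording as (channels × samples, fs).  Requires mne."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF support requires the 'mne' package "
                          "(install aadrl[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])


def write_trace(path, trace: DecisionTrace) -> None:
    """Episode trace as TSV: t_ms, true side, predicted side, reward."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("t_ms\ttrue\tpred\treward\n")
        for t, yt, yp, r in zip(trace.t_ms, trace.true, trace.pred, trace.rewards):
            fh.write(f"{t:.3f}\t{SIDE_CHARS[int(yt)]}\t{SIDE_CHARS[int(yp)]}\t{int(r)}\n")


def write_curve(path, t_ms: np.ndarray, curve: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([t_ms, curve]), delimiter="\t",
               header="t_ms\tcumulative_accuracy", comments="")
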