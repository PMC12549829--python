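"""Recording container, file I/O, and preprocessing (downsampling, notch).

The analysis pipeline assumes recordings acquired at a high rate (e.g. 4 kHz)
that are brought to a 400 Hz analysis rate and cleaned of mains interference
before any spectral or burst analysis.  Both steps are linear, zero-phase
operations so that burst timing is not shifted by filtering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, InvalidParameterError

__all__ = [
    "Recording",
    "PreprocessParams",
    "read_recording",
    "write_recording",
    "downsample",
    "notch",
    "preprocess",
]


@dataclass
class Recording:
    """Multichannel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per row of ``samples``.
    state : str, optional
        Free-text state annotation (e.g. ``"parkinsonian"``).
    event_mask : ndarray of bool, shape (n_samples,), optional
        Per-sample flag marking high-amplitude event segments.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    state: str | None = None
    event_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise InvalidParameterError("samples must be a 2-D channel x time array")
        if not np.isfinite(self.samples).all():
            raise InvalidParameterError("samples contain non-finite values")
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidParameterError("channel labels must be unique")
        if self.event_mask is not None:
            self.event_mask = np.asarray(self.event_mask, dtype=bool)
            if self.event_mask.shape != (self.samples.shape[1],):
                raise InvalidParameterError("event_mask length must match samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing settings: analysis rate and notch comb.

    Notches are applied at ``k * line_freq`` for every harmonic up to
    ``min(notch_max_freq, Nyquist)``.
    """

    target_fs: float = 400.0
    line_freq: float = 50.0
    notch_max_freq: float = 200.0
    notch_bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.target_fs <= 0:
            raise InvalidParameterError("target_fs must be positive")
        if self.line_freq <= 0:
            raise InvalidParameterError("line_freq must be positive")
        if self.line_freq >= self.target_fs / 2:
            raise InvalidParameterError(
                f"line_freq {self.line_freq} must lie below target Nyquist "
                f"{self.target_fs / 2}"
            )
        if self.notch_bandwidth <= 0:
            raise InvalidParameterError("notch_bandwidth must be positive")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV: ``time,<label>,...`` with time in seconds."""
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.insert(0, "time", rec.times)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from CSV or EDF.

    The CSV dialect is comma-separated with header ``time,<label>,...`` and
    time in seconds; the time column must be uniformly sampled.  EDF reading
    requires the optional ``mne`` dependency and converts to microvolts.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "edf":
        return _read_edf(path)
    raise InvalidParameterError(f"unknown format {format!r}")


def _read_csv(path: Path) -> Recording:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise FormatError(f"{path}: expected header 'time,<label>,...'")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values (unequal channel lengths?)")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt.mean(), rtol=1e-4, atol=1e-9 * dt.mean()):
        raise FormatError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt.mean()
    labels = list(df.columns[1:])
    return Recording(df[labels].to_numpy(dtype=float).T, fs, labels)


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data, fs, list(raw.ch_names))


def write_provenance(path: str | Path, record: dict) -> Path:
    """Write a JSON provenance sidecar (input, parameters, versions)."""
    import scipy

    path = Path(path)
    record = dict(record)
    record.setdefault(
        "versions", {"numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__}
    )
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def downsample(rec: Recording, target_fs: float) -> Recording:
    """Resample to ``target_fs`` with polyphase anti-alias filtering.

    Rational rate ratios are handled exactly via up/down factors; the
    anti-alias filter is the Kaiser-window FIR design used by
    :func:`scipy.signal.resample_poly`.  Event masks are resampled by
    nearest neighbour (they are categorical).
    """
    if target_fs <= 0:
        raise InvalidParameterError("target_fs must be positive")
    if target_fs > rec.fs:
        raise InvalidParameterError(
            f"target_fs {target_fs} exceeds recording rate {rec.fs}"
        )
    if target_fs == rec.fs:
        return replace(rec)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(rec.samples, up, down, axis=1)
    mask = None
    if rec.event_mask is not None:
        idx = np.minimum(
            np.round(np.arange(out.shape[1]) * rec.fs / target_fs).astype(int),
            rec.n_samples - 1,
        )
        mask = rec.event_mask[idx]
    return Recording(out, float(target_fs), list(rec.channel_labels), rec.state, mask)


def notch(rec: Recording, params: PreprocessParams | None = None) -> Recording:
    """Remove mains interference and its harmonics.

    One second-order IIR notch per harmonic of ``line_freq`` up to
    ``min(notch_max_freq, Nyquist)``, each applied forward-backward
    (zero phase, no group delay).  Signal length is preserved.
    """
    params = params or PreprocessParams()
    nyq = rec.fs / 2
    if params.line_freq >= nyq:
        raise InvalidParameterError(
            f"line_freq {params.line_freq} is at or above Nyquist {nyq}"
        )
    out = rec.samples.copy()
    f0 = params.line_freq
    k = 1
    while k * f0 < min(params.notch_max_freq + f0 / 2, nyq * 0.999):
        fk = k * f0
        if fk > params.notch_max_freq:
            break
        b, a = signal.iirnotch(fk, fk / params.notch_bandwidth, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
        k += 1
    return Recording(out, rec.fs, list(rec.channel_labels), rec.state, rec.event_mask)


def preprocess(rec: Recording, params: PreprocessParams | None = None) -> Recording:
    """Full preprocessing: downsample to the analysis rate, then notch."""
    params = params or PreprocessParams()
    if params.target_fs > rec.fs:
        raise InvalidParameterError(
            f"target_fs {params.target_fs} exceeds recording rate {rec.fs}"
        )
    return notch(downsample(rec, params.target_fs), params)
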