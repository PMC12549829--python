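"""Welch PSD estimation, beta-peak identification, spectrograms, and
noise density at mains harmonics.

Power spectra use Welch's method with Hann windows (default 4 s, 50%
overlap: 0.25 Hz resolution at a 400 Hz analysis rate) and density
normalisation, so the integral of the PSD over frequency approximates the
signal variance for stationary inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, InvalidParameterError
from .io_preprocess import Recording

__all__ = [
    "SpectralEstimate",
    "BetaBand",
    "welch_psd",
    "find_beta_peak",
    "spectrogram",
    "noise_density_at",
]

DEFAULT_WINDOW_S = 4.0
DEFAULT_OVERLAP = 0.5


@dataclass
class SpectralEstimate:
    """Per-channel Welch PSD on a common frequency grid (uV^2/Hz)."""

    freqs: np.ndarray  # (n_freqs,), 0 .. Nyquist
    psd: np.ndarray  # (n_channels, n_freqs)
    window_s: float
    overlap_frac: float
    n_segments: int
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidParameterError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise InvalidParameterError("psd must be nonnegative")

    @property
    def df(self) -> float:
        """Grid resolution in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BetaBand:
    """Beta frequency band edges; 13-30 Hz is the conventional definition."""

    f_lo: float = 13.0
    f_hi: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise InvalidParameterError("need 0 < f_lo < f_hi")


def welch_psd(
    rec: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> SpectralEstimate:
    """Welch power spectral density with Hann windows, per channel."""
    nperseg = int(round(window_s * rec.fs))
    if nperseg < 16:
        raise InvalidParameterError("window must span at least 16 samples")
    if not 0 <= overlap_frac < 1:
        raise InvalidParameterError("overlap_frac must lie in [0, 1)")
    if rec.n_samples < nperseg:
        raise InsufficientDataError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{nperseg}-sample window"
        )
    noverlap = int(round(nperseg * overlap_frac))
    freqs, psd = signal.welch(
        rec.samples, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density", axis=1,
    )
    step = nperseg - noverlap
    n_segments = 1 + (rec.n_samples - nperseg) // step
    return SpectralEstimate(
        freqs, psd, window_s, overlap_frac, n_segments, list(rec.channel_labels)
    )


def _loglog_background(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Least-squares 1/f-type background: a line in log10(psd) vs log10(f)."""
    lf = np.log10(freqs)
    lp = np.log10(np.maximum(psd, 1e-300))
    slope, intercept = np.polyfit(lf, lp, 1)
    return 10.0 ** (intercept + slope * lf)


def find_beta_peak(
    est: SpectralEstimate,
    band: BetaBand | None = None,
    min_prominence: float = 0.2,
) -> list[float | None]:
    """Locate the dominant beta-band PSD peak per channel.

    A candidate is a local maximum of the PSD within the band whose power
    exceeds the locally detrended 1/f background by at least
    ``min_prominence`` (a ratio: 0.2 means 20% above background).  Returns
    the frequency of the strongest qualifying candidate per channel, or
    ``None`` when no local maximum stands out of the background — which is
    the correct answer for a monotone 1/f spectrum.
    """
    band = band or BetaBand()
    if band.f_lo < est.freqs[0] or band.f_hi > est.freqs[-1]:
        raise InvalidParameterError("beta band outside the frequency grid")
    sel = (est.freqs >= band.f_lo) & (est.freqs <= band.f_hi)
    if sel.sum() < 3:
        raise InvalidParameterError("beta band spans fewer than 3 grid points")
    f_band = est.freqs[sel]
    peaks: list[float | None] = []
    for p in est.psd:
        p_band = p[sel]
        if np.all(p_band == 0):
            peaks.append(None)
            continue
        background = _loglog_background(f_band, p_band)
        # local maxima strictly inside the band
        idx, _ = signal.find_peaks(p_band)
        qualified = [
            i for i in idx if p_band[i] >= (1.0 + min_prominence) * background[i]
        ]
        if not qualified:
            peaks.append(None)
        else:
            best = max(qualified, key=lambda i: p_band[i])
            peaks.append(float(f_band[best]))
    return peaks


def spectrogram(
    rec: Recording,
    window_s: float = 1.0,
    overlap_frac: float = 0.5,
    f_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectrogram, truncated at ``f_max``.

    Returns ``(freqs, times, power)`` where power has shape
    (n_channels, n_freqs, n_times).
    """
    nyq = rec.fs / 2
    f_max = nyq if f_max is None else f_max
    if f_max > nyq:
        raise InvalidParameterError(f"f_max {f_max} exceeds Nyquist {nyq}")
    nperseg = int(round(window_s * rec.fs))
    if nperseg < 16:
        raise InvalidParameterError("window must span at least 16 samples")
    if rec.n_samples < nperseg:
        raise InsufficientDataError("recording shorter than one window")
    noverlap = int(round(nperseg * overlap_frac))
    freqs, times, power = signal.spectrogram(
        rec.samples, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density", axis=1,
    )
    keep = freqs <= f_max
    return freqs[keep], times, power[:, keep, :]


def noise_density_at(
    rec: Recording,
    freqs_of_interest: list[float] | None = None,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP,
) -> np.ndarray:
    """Amplitude spectral density (uV/sqrt(Hz)) at the requested frequencies.

    Defaults to the mains fundamental and harmonics up to 200 Hz; values are
    sqrt(Welch PSD) linearly interpolated at each frequency, per channel.
    Returns shape (n_channels, n_freqs_of_interest).
    """
    if freqs_of_interest is None:
        freqs_of_interest = [50.0, 100.0, 150.0, 200.0]
    nyq = rec.fs / 2
    for f in freqs_of_interest:
        if f > nyq:
            raise InvalidParameterError(f"frequency {f} above Nyquist {nyq}")
    est = welch_psd(rec, window_s, overlap_frac)
    asd = np.sqrt(est.psd)
    return np.vstack(
        [np.interp(freqs_of_interest, est.freqs, a) for a in asd]
    )
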