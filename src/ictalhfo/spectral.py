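"""Time-frequency decomposition and spectral utilities.

Morlet wavelet scaleograms on logarithmic frequency grids, 1/f
normalization against the theoretical background spectrum S(f) = f^-1,
dominant-frequency tracking, and band-limited amplitude envelopes.
These are the primitives for both seizure-wide spectrograms and
per-discharge spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TimeFrequency",
    "NormalizedSpectrum",
    "log_spaced_freqs",
    "default_freq_grid",
    "morlet_scaleogram",
    "normalize_one_over_f",
    "dominant_frequency",
    "band_envelope",
]

#: number of logarithmically spaced frequency bins in the default grids
N_FREQ_BINS = 107


@dataclass
class TimeFrequency:
    """Magnitude scaleogram on a (frequency x time) grid.

    ``edge_valid`` flags, per frequency, the samples that are at least
    half a wavelet length away from the signal edges; edge samples are
    kept (not silently dropped) but flagged for downstream consumers.
    """

    magnitude: np.ndarray  # (n_freqs, n_times), >= 0
    freqs_hz: np.ndarray  # strictly increasing
    times_s: np.ndarray
    fs: float
    edge_valid: np.ndarray | None = None  # (n_freqs, n_times) bool

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.magnitude.shape != (self.freqs_hz.size, self.times_s.size):
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} does not match "
                f"{self.freqs_hz.size} freqs x {self.times_s.size} times"
            )
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class NormalizedSpectrum:
    """Per-frequency relative power distribution p(s) on a fixed grid.

    ``p_s`` sums to one; ``s_raw`` retains the raw (already 1/f
    normalized) magnitude before distribution-normalization, for
    consumers that need the non-probability form.
    """

    p_s: np.ndarray
    freqs_hz: np.ndarray
    s_raw: np.ndarray | None = None
    reference: str = "S(f) = f^-1"

    def __post_init__(self) -> None:
        self.p_s = np.asarray(self.p_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.p_s.shape != self.freqs_hz.shape:
            raise ValueError("p_s and freqs_hz must have the same shape")
        if np.any(self.p_s < 0):
            raise ValueError("p_s must be non-negative")
        if abs(self.p_s.sum() - 1.0) > 1e-9:
            raise ValueError("p_s must sum to 1 within 1e-9")


def log_spaced_freqs(fmin: float, fmax: float, n: int = N_FREQ_BINS) -> np.ndarray:
    """Logarithmically spaced frequency grid, endpoints inclusive."""
    if fmin <= 0 or fmax <= fmin:
        raise ValueError("require 0 < fmin < fmax")
    return np.geomspace(fmin, fmax, n)


def default_freq_grid(fs: float) -> np.ndarray:
    """Default seizure-wide grid: 107 log bins, 1-200 Hz for macro-rate
    signals and 1-850 Hz for micro-rate signals (fs >= 1700 Hz)."""
    fmax = 850.0 if fs >= 1700.0 else 200.0
    return log_spaced_freqs(1.0, fmax, N_FREQ_BINS)


def morlet_scaleogram(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
) -> TimeFrequency:
    """Magnitude of the n-cycle Morlet wavelet transform.

    Implemented by frequency-domain multiplication with Gaussian
    (analytic) kernels centered at each grid frequency, with spectral
    width f0 / n_cycles.  The amplitude convention is envelope-like: a
    unit-amplitude sinusoid at a grid frequency yields magnitude ~1 at
    that bin.

    Parameters
    ----------
    signal : 1-D voltage series
    fs : sampling rate, Hz
    freqs : strictly increasing grid; defaults to :func:`default_freq_grid`
    n_cycles : wavelet width in cycles (default 5)
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if freqs is None:
        freqs = default_freq_grid(fs)
    freqs = np.asarray(freqs, dtype=float)
    too_high = np.nonzero(freqs >= fs / 2)[0]
    if too_high.size:
        i = int(too_high[0])
        raise ValueError(
            f"frequency bin {i} ({freqs[i]:g} Hz) is at or above Nyquist ({fs / 2:g} Hz)"
        )
    n = x.size
    xf = np.fft.fft(x)
    f_axis = np.fft.fftfreq(n, d=1.0 / fs)
    mag = np.empty((freqs.size, n), dtype=float)
    # chunk over frequencies to bound memory on long recordings
    chunk = max(1, int(2e7 // max(n, 1)))
    pos = f_axis > 0
    for i0 in range(0, freqs.size, chunk):
        f0 = freqs[i0 : i0 + chunk, None]
        sigma_f = f0 / n_cycles
        kern = np.zeros((f0.size, n))
        kern[:, pos] = 2.0 * np.exp(
            -0.5 * ((f_axis[pos][None, :] - f0) / sigma_f) ** 2
        )
        mag[i0 : i0 + chunk] = np.abs(np.fft.ifft(xf[None, :] * kern, axis=1))
    times = np.arange(n) / fs
    # half a wavelet length: n_cycles / (2 f0) seconds
    edge_valid = np.ones((freqs.size, n), dtype=bool)
    half_len = np.round(n_cycles / (2.0 * freqs) * fs).astype(int)
    for i, h in enumerate(half_len):
        if h > 0:
            edge_valid[i, :h] = False
            edge_valid[i, n - h :] = False
    return TimeFrequency(mag, freqs, times, float(fs), edge_valid)


def normalize_one_over_f(tf: TimeFrequency, *, invert: bool = False) -> TimeFrequency:
    """Divide each frequency row by the theoretical spectrum S(f) = 1/f,
    i.e. multiply by f.  ``invert=True`` undoes the normalization."""
    if np.any(tf.freqs_hz <= 0):
        raise ValueError("1/f normalization requires strictly positive frequencies")
    f = tf.freqs_hz[:, None]
    mag = tf.magnitude / f if invert else tf.magnitude * f
    return replace(tf, magnitude=mag)


def dominant_frequency(tf: TimeFrequency, fs: float) -> np.ndarray:
    """Per-time-bin argmax frequency, boxcar-smoothed.

    The raw argmax series is smoothed by a moving average whose window
    is round(fs / 8) samples (125 ms of data), then snapped back to the
    nearest grid frequency so the output always lies on the grid.
    """
    if not np.any(tf.magnitude):
        raise ValueError("dominant frequency undefined for an all-zero scaleogram")
    raw = tf.freqs_hz[np.argmax(tf.magnitude, axis=0)]
    win = max(1, int(round(fs / 8.0)))
    smoothed = uniform_filter1d(raw, size=win, mode="nearest") if win > 1 else raw
    # snap to nearest grid bin (log-spaced grid: nearest in linear freq)
    idx = np.searchsorted(tf.freqs_hz, smoothed)
    idx = np.clip(idx, 1, tf.freqs_hz.size - 1)
    lower = tf.freqs_hz[idx - 1]
    upper = tf.freqs_hz[idx]
    idx -= (smoothed - lower) < (upper - smoothed)
    return tf.freqs_hz[idx]


def band_envelope(signal: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous amplitude in a band: |analytic signal| of the
    zero-phase 4th-order Butterworth band-passed input."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band {band} for fs={fs}")
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(signal, dtype=float))
    return np.abs(hilbert(filtered))
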