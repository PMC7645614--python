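"""Per-discharge complexity metrics.

Each detected discharge is summarized by a short voltage window (296
samples on microelectrodes, 98 on macroelectrodes, centered on the
discharge peak) and scored with:

* differential entropy h(V): Shannon entropy of the voltage histogram,
  scaled by 1/n (time-domain complexity);
* spectral entropy h(S): Shannon entropy of the 1/f-normalized,
  distribution-normalized discharge spectrum (spectral complexity;
  maximum log2(n_bins) for a flat spectrum);
* spectral mode: the most prevalent frequency in the metric band;
* fast-ripple index (micro): proportion of the normalized spectrum
  above 250 Hz; ripple index (macro): proportion between 80 and 200 Hz.

Smooth narrowband oscillations concentrate spectral mass and score low;
jittered population bursts spread it and score high.
"""

from __future__ import annotations

import warnings

import numpy as np

from .spectral import NormalizedSpectrum, morlet_scaleogram, normalize_one_over_f

__all__ = [
    "MICRO_WINDOW_SAMPLES",
    "MACRO_WINDOW_SAMPLES",
    "micro_metric_grid",
    "macro_metric_grid",
    "discharge_spectrum",
    "differential_entropy",
    "spectral_entropy",
    "spectral_indices",
    "complexity_metrics",
]

MICRO_WINDOW_SAMPLES = 296  # ~99 ms at 3 kHz
MACRO_WINDOW_SAMPLES = 98  # ~196 ms at 500 Hz
FAST_RIPPLE_EDGE_HZ = 250.0
RIPPLE_BAND_HZ = (80.0, 200.0)


def micro_metric_grid() -> np.ndarray:
    """107 log-spaced bins spanning 100-800 Hz (microelectrode metric band)."""
    return np.geomspace(100.0, 800.0, 107)


def macro_metric_grid() -> np.ndarray:
    """50 log-spaced bins spanning 1-250 Hz.  The top edge equals the
    macro Nyquist, where a Morlet atom is degenerate, so the grid is
    built endpoint-exclusive (sup < 250 Hz)."""
    return np.geomspace(1.0, 250.0, 51)[:-1]


def discharge_spectrum(window: np.ndarray, fs: float, source: str) -> NormalizedSpectrum:
    """1/f-normalized, distribution-normalized spectrum of one discharge.

    The window is reflection-padded before the Morlet transform to keep
    wavelet edge effects out of the estimate; magnitude is averaged
    over the central (original) samples.
    """
    w = np.asarray(window, dtype=float)
    expected = MICRO_WINDOW_SAMPLES if source == "micro" else MACRO_WINDOW_SAMPLES
    if source == "micro":
        freqs = micro_metric_grid()
    elif source == "macro":
        freqs = macro_metric_grid()
    else:
        raise ValueError(f"source must be 'micro' or 'macro', got {source!r}")
    if w.size != expected:
        raise ValueError(f"{source} discharge window must have {expected} samples, got {w.size}")
    if not np.all(np.isfinite(w)):
        raise ValueError("discharge window contains non-finite values")
    pad = 2 * w.size
    padded = np.pad(w - w.mean(), pad, mode="reflect")
    tf = normalize_one_over_f(morlet_scaleogram(padded, fs, freqs))
    raw = tf.magnitude[:, pad : pad + w.size].mean(axis=1)
    total = raw.sum()
    if total == 0:
        raise ValueError("all-zero window has no spectrum")
    return NormalizedSpectrum(p_s=raw / total, freqs_hz=freqs, s_raw=raw)


def differential_entropy(window: np.ndarray, n_hist_bins: int = 32) -> float:
    """Time-domain complexity: h(V) = -(1/n) sum p(v) log2 p(v).

    p(v) is the histogram of voltages over ``n_hist_bins`` equal-width
    bins spanning the window's range; the 1/n scaling is retained as a
    constant within each electrode class.  A constant window occupies a
    single bin and scores 0 (with a warning).
    """
    v = np.asarray(window, dtype=float)
    n = v.size
    if n <= 1:
        raise ValueError("window must have more than one sample")
    if v.max() == v.min():
        warnings.warn("constant window: zero voltage range, entropy 0", stacklevel=2)
        return 0.0
    counts, _ = np.histogram(v, bins=n_hist_bins)
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum() / n)


def spectral_entropy(spec: NormalizedSpectrum | np.ndarray, formula: str = "shannon") -> float:
    """Spectral complexity in bits: h(S) = -sum p(s) log2 p(s).

    Maximal (log2 of the number of bins) for a flat spectrum, 0 when
    all power sits in one bin.  ``formula="as_printed"`` evaluates
    -sum p(s) log2(s) against the raw (non-normalized) spectrum
    instead; it is provided for comparison only and does not attain the
    log2(n_bins) maximum.
    """
    if isinstance(spec, NormalizedSpectrum):
        p = spec.p_s
        raw = spec.s_raw
    else:
        p = np.asarray(spec, dtype=float)
        raw = None
        if np.any(p < 0):
            raise ValueError("spectrum must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum must be distribution-normalized (sum to 1 within 1e-9)")
    if formula == "shannon":
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())
    if formula == "as_printed":
        if raw is None:
            raise ValueError("as_printed form requires the raw spectrum (NormalizedSpectrum)")
        sel = (p > 0) & (raw > 0)
        return float(-(p[sel] * np.log2(raw[sel])).sum())
    raise ValueError(f"unknown formula {formula!r}")


def spectral_indices(spec: NormalizedSpectrum, source: str) -> tuple[float, float]:
    """(spectral mode, band index) of a per-discharge spectrum.

    Micro: mode is the argmax frequency on the 100-800 Hz grid and the
    index is the fast-ripple index, the proportion of the normalized
    spectrum above 250 Hz.  Macro: the grid spans 1-250 Hz and the
    index is the ripple index, the proportion between 80 and 200 Hz.
    """
    f = spec.freqs_hz
    if source == "micro":
        ref = micro_metric_grid()
    elif source == "macro":
        ref = macro_metric_grid()
    else:
        raise ValueError(f"source must be 'micro' or 'macro', got {source!r}")
    if f.size != ref.size or not np.allclose(f, ref):
        raise ValueError(f"spectrum grid does not match the {source} metric grid")
    mode = float(f[int(np.argmax(spec.p_s))])
    if source == "micro":
        index = float(spec.p_s[f > FAST_RIPPLE_EDGE_HZ].sum())
    else:
        lo, hi = RIPPLE_BAND_HZ
        index = float(spec.p_s[(f >= lo) & (f <= hi)].sum())
    return mode, index


def complexity_metrics(window: np.ndarray, fs: float, source: str) -> dict[str, float]:
    """All per-discharge complexity metrics for one window."""
    spec = discharge_spectrum(window, fs, source)
    mode, index = spectral_indices(spec, source)
    out = {
        "differential_entropy_bits": differential_entropy(window),
        "spectral_entropy_bits": spectral_entropy(spec),
        "spectral_mode_hz": mode,
    }
    out["fast_ripple_index" if source == "micro" else "ripple_index"] = index
    return out
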