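"""Spike-LFP phase coupling and circular statistics.

Phases are extracted at multiunit event times from the analytic signal
of the LFP band-passed at +-5 Hz around the dominant frequency (96th
order zero-phase FIR).  Coupling differences between pre- and
post-recruitment epochs are tested with a permutation Kuiper test; the
bimodal-vs-unimodal dispersion contrast uses a two-sample concentration
F-test after angle-doubling the bimodal sample (which folds antipodal
modes onto one).

Phase convention: cosine phase, zero at the band-passed signal's peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert
from scipy.stats import f as f_dist

__all__ = [
    "PhaseSample",
    "KuiperResult",
    "phase_at_events",
    "phase_histogram",
    "kuiper_statistic",
    "kuiper_permutation_test",
    "concentration_test_doubled",
    "rayleigh_test",
    "resultant_length",
]

FIR_ORDER = 96
HALF_BANDWIDTH_HZ = 5.0


@dataclass
class PhaseSample:
    phases: np.ndarray  # radians in [-pi, pi)
    f0_hz: float
    half_bandwidth_hz: float = HALF_BANDWIDTH_HZ
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.size and (self.phases.min() < -np.pi or self.phases.max() >= np.pi):
            raise ValueError("phases must lie in [-pi, pi)")


@dataclass
class KuiperResult:
    V: float
    D_plus: float
    D_minus: float
    p: float
    null_V: np.ndarray = field(repr=False)
    m: int = 0
    n_perm: int = 0


def _wrap(phases: np.ndarray) -> np.ndarray:
    return np.mod(np.asarray(phases, dtype=float) + np.pi, 2 * np.pi) - np.pi


def phase_at_events(
    lfp: np.ndarray,
    fs: float,
    f0: float,
    event_times: np.ndarray,
    half_bandwidth_hz: float = HALF_BANDWIDTH_HZ,
    epoch: str | None = None,
) -> PhaseSample:
    """Instantaneous phase of the dominant-frequency band at event times.

    Zero-phase 96th-order FIR band-pass at [f0-5, f0+5] Hz, analytic
    signal via the Hilbert transform, phase read at the nearest sample.
    """
    lfp = np.asarray(lfp, dtype=float)
    if f0 + half_bandwidth_hz >= fs / 2:
        raise ValueError(f"band edge {f0 + half_bandwidth_hz} Hz is at or above Nyquist")
    if f0 - half_bandwidth_hz <= 0:
        raise ValueError("lower band edge must be positive")
    ev = np.asarray(event_times, dtype=float)
    idx = np.round(ev * fs).astype(int)
    bad = (idx < 0) | (idx >= lfp.size)
    if bad.any():
        raise ValueError(f"event times outside the signal span: {ev[bad].tolist()}")
    taps = firwin(
        FIR_ORDER + 1,
        [f0 - half_bandwidth_hz, f0 + half_bandwidth_hz],
        pass_zero=False,
        fs=fs,
    )
    filtered = filtfilt(taps, [1.0], lfp)
    phase = np.angle(hilbert(filtered))
    return PhaseSample(_wrap(phase[idx]), f0, half_bandwidth_hz, epoch)


def phase_histogram(phases: np.ndarray, n_bins: int = 36) -> tuple[np.ndarray, np.ndarray]:
    """Counts over equal-width circular bins (default 36, i.e. 10 deg).

    Returns (counts, bin_edges) with edges in radians over [-pi, pi)."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(_wrap(phases), bins=edges)
    return counts, edges


def kuiper_statistic(
    sample_a: np.ndarray, sample_b: np.ndarray, as_printed: bool = False
) -> tuple[float, float, float]:
    """Two-sample Kuiper statistic on the circle.

    D+ = sup(F_a - F_b), D- = sup(F_b - F_a) over the pooled sample
    (with the zero level at the wrap point included), V = D+ + D-.
    V depends only on the cyclic order of the pooled sample, so it is
    invariant under common rotations of both samples.  ``as_printed``
    returns the subtraction variant V = D+ - D- instead.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    pooled.sort()
    d = np.searchsorted(a, pooled, side="right") / a.size - np.searchsorted(
        b, pooled, side="right"
    ) / b.size
    d_plus = max(float(d.max()), 0.0)
    d_minus = max(float(-d.min()), 0.0)
    v = d_plus - d_minus if as_printed else d_plus + d_minus
    return v, d_plus, d_minus


def _kuiper_from_labels(sorted_labels: np.ndarray, m: int) -> float:
    """V for an m/m split given the a-membership mask of the drawn
    points in pooled sorted order (path formulation of the ECDF gap)."""
    step = np.where(sorted_labels, 1.0 / m, -1.0 / m)
    path = np.cumsum(step)
    return max(path.max(), 0.0) + max(-path.min(), 0.0)


def kuiper_permutation_test(
    pre: np.ndarray,
    post: np.ndarray,
    m: int = 2000,
    n_perm: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    as_printed: bool = False,
) -> KuiperResult:
    """Permutation-calibrated Kuiper test for a change in the spike-phase
    distribution between epochs.

    The observed V is computed on the full samples.  The null is built
    by pooling both samples and, for each permutation, drawing two
    disjoint m-sized subsets without replacement and computing V
    between them.  p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    m_eff = min(m, pre.size, post.size)
    if m_eff < m:
        warnings.warn(f"subsample size reduced from {m} to {m_eff}", stacklevel=2)
    if m_eff < 10:
        raise ValueError(f"subsample size {m_eff} < 10; test uninformative")
    if rng is None:
        rng = np.random.default_rng(seed)
    v_obs, d_plus, d_minus = kuiper_statistic(pre, post, as_printed=as_printed)
    pooled = np.concatenate([pre, post])
    n_pool = pooled.size
    order_of = np.empty(n_pool, dtype=int)
    order_of[np.argsort(pooled, kind="stable")] = np.arange(n_pool)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.permutation(n_pool)[: 2 * m_eff]
        is_a = np.zeros(2 * m_eff, dtype=bool)
        is_a[:m_eff] = True
        pos = order_of[draw]
        o = np.argsort(pos, kind="stable")
        v = _kuiper_from_labels(is_a[o], m_eff)
        if as_printed:
            # recompute the signed variant from the path extrema
            step = np.where(is_a[o], 1.0 / m_eff, -1.0 / m_eff)
            path = np.cumsum(step)
            v = max(path.max(), 0.0) - max(-path.min(), 0.0)
        null[i] = v
    p = (1.0 + np.sum(null >= v_obs)) / (1.0 + n_perm)
    return KuiperResult(v_obs, d_plus, d_minus, float(p), null, m_eff, n_perm)


def resultant_length(phases: np.ndarray) -> float:
    """Mean resultant length of a circular sample."""
    phases = np.asarray(phases, dtype=float)
    return float(np.abs(np.mean(np.exp(1j * phases))))


def concentration_test_doubled(
    bimodal_phases: np.ndarray, unimodal_phases: np.ndarray
) -> tuple[float, float]:
    """Two-sample concentration comparison after angle-doubling.

    The bimodal sample is angle-doubled (2*theta mod 2*pi), folding its
    antipodal modes onto one so both samples are unimodal and their
    concentrations comparable "on the interval [0, pi)".  The test is
    the standard circular-dispersion F ratio:
    F = [(n1 - R1)/(n1 - 1)] / [(n2 - R2)/(n2 - 1)] ~ F(n1-1, n2-1),
    two-sided.  Valid for reasonably concentrated samples.
    """
    b = np.asarray(bimodal_phases, dtype=float)
    u = np.asarray(unimodal_phases, dtype=float)
    if b.size < 10 or u.size < 10:
        raise ValueError("need at least 10 phases in each sample")
    doubled = _wrap(2.0 * b)
    r1 = resultant_length(doubled)
    r2 = resultant_length(u)
    if r1 < 1e-8 and r2 < 1e-8:
        raise ValueError("both samples have vanishing resultant; concentrations undefined")
    n1, n2 = doubled.size, u.size
    num = (n1 - n1 * r1) / (n1 - 1)
    den = (n2 - n2 * r2) / (n2 - 1)
    if den == 0:
        return float("inf"), 0.0
    f = num / den
    cdf = f_dist.cdf(f, n1 - 1, n2 - 1)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(f), float(min(p, 1.0))


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test p-value for circular uniformity (Berens/Zar
    approximation), used as a symmetry check on generated trains."""
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise ValueError("empty sample")
    r = resultant_length(phases)
    z = n * r**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * r) ** 2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))
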