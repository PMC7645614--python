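"""Synthetic seizure recordings with known ground truth.

Emulates the phenomenology of rhythmic-onset focal seizures recorded
simultaneously on penetrating microelectrodes and clinical
macroelectrodes:

* multichannel LFP riding on an approximately f^-1 background;
* a slowly propagating ictal wavefront (a surge of tonic multiunit
  firing) crossing the micro channels with a fixed channel-to-channel
  delay, which splits each channel's discharges into *pre-* and
  *post-recruitment* epochs;
* pre-recruitment discharges carrying a narrowband gamma oscillation
  (default ~55 Hz, drifting upward until recruitment) with **bimodal**
  spike-phase coupling — the signature of intact feed-forward
  inhibition sculpting population firing;
* post-recruitment discharges built from temporally jittered population
  spikes (paroxysmal depolarizing shifts, PDS), which summate into
  broadband high-frequency (BHF) LFP with **unimodal** coupling;
* macro channels formed as spatially mixed, low-pass filtered,
  decimated projections of local activity.  Core macro channels see the
  recruited micro activity; penumbral macro channels receive narrowband
  gamma discharges throughout and never contain PDS bursts.

Fixing the seed makes every output bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.special import i0

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticRecording",
    "simulate_recording",
    "coupled_spike_times",
    "pds_burst",
    "biphasic_spike",
    "shaped_noise",
]


@dataclass
class SimConfig:
    """Generator parameters.  Defaults are the package's stated world:
    a 60 s recording whose seizure starts at 10 s and recruits the
    micro array around 30 s."""

    duration_s: float = 60.0
    fs_micro: float = 3000.0
    fs_macro: float = 500.0
    n_micro_channels: int = 8
    n_macro_channels: int = 12
    onset_s: float = 10.0  # first discharge / seizure onset
    wavefront_time_s: float = 30.0  # wavefront reaches micro channel 0
    wavefront_delay_s: float = 0.1  # channel-to-channel propagation delay
    discharge_rate_hz: float = 1.5  # rhythmic discharges, ~1-2 Hz
    gamma_freq_hz: float = 55.0  # pre-recruitment oscillation center
    gamma_drift_hz_per_s: float = 0.3  # dominant frequency rise to recruitment
    coupling_kappa_pre: float = 2.0  # bimodal concentration
    coupling_kappa_post: float = 2.0  # unimodal concentration
    pds_jitter_ms: float = 2.0  # SD of population-spike jitter (summated energy ~70-200+ Hz)
    n_neurons_per_channel: int = 100
    background_exponent: float = 1.0  # f^-n background
    noise_scale: float = 10e-6  # background RMS, volts (discharges are ~25-35x larger)
    seed: int = 0
    # amplitude / rate details of the stated world
    gamma_amp_v: float = 250e-6
    rhythm_amp_v: float = 300e-6  # continuous low-frequency ictal rhythm
    slow_wave_amp_v: float = 150e-6  # sharp transient riding each rhythm peak
    spike_amp_v: float = 50e-6
    penumbra_gain: float = 1.0  # penumbral discharge amplitude is a free parameter
    pre_spike_rate_hz: float = 900.0  # multiunit burst rate within pre discharges
    post_spike_rate_hz: float = 150.0  # coupled multiunit rate within post discharges
    tonic_rate_hz: float = 500.0  # wavefront tonic surge (dominant firing event)
    tonic_duration_s: float = 2.5
    baseline_rate_hz: float = 5.0
    burst_sigma_s: float = 0.04  # gamma burst Gaussian envelope SD

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("fs_micro", "fs_macro", "gamma_freq_hz", "noise_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.discharge_rate_hz < 0:
            raise ValueError("discharge_rate_hz must be non-negative")
        if self.gamma_freq_hz >= self.fs_macro / 2:
            raise ValueError(
                f"gamma_freq_hz={self.gamma_freq_hz} aliases on macro channels "
                f"(>= fs_macro/2 = {self.fs_macro / 2})"
            )
        if not (0 < self.wavefront_time_s < self.duration_s):
            raise ValueError("wavefront_time_s must lie inside the recording")
        if min(self.coupling_kappa_pre, self.coupling_kappa_post) < 0:
            raise ValueError("coupling concentrations must be >= 0")
        if self.n_micro_channels < 1 or self.n_macro_channels < 1:
            raise ValueError("need at least one channel of each kind")


@dataclass
class GroundTruth:
    recruitment_time_s: np.ndarray  # per micro channel
    discharges: pd.DataFrame  # columns: time_s, channel, epoch
    discharge_times_s: np.ndarray  # seizure-wide rhythmic discharge times
    spike_times_s: dict[int, np.ndarray]  # per micro channel
    spike_labels: dict[int, np.ndarray]  # baseline|tonic|pre_bimodal|post_unimodal
    macro_channel_domain: list[str]  # "core" | "penumbra" per macro channel
    dominant_freq_truth_hz: np.ndarray  # at fs of dominant_freq_times_s
    dominant_freq_times_s: np.ndarray


@dataclass
class SyntheticRecording:
    micro: np.ndarray  # (n_micro, n_samples) volts
    fs_micro: float
    macro: np.ndarray  # (n_macro, n_samples) volts
    fs_macro: float
    micro_channel_ids: list[int] = field(default_factory=list)
    macro_channel_ids: list[int] = field(default_factory=list)


def biphasic_spike(fs: float, dur_ms: float = 1.4, amp_v: float = 50e-6) -> np.ndarray:
    """Extracellular-convention biphasic (negative-leading) action
    potential template, 1-2 ms long, with energy in the 300-3000 Hz
    multiunit band."""
    n = max(4, int(round(dur_ms * 1e-3 * fs)))
    t = np.arange(n) / n
    return -amp_v * np.sin(2 * np.pi * t) * np.hanning(n)


def shaped_noise(
    n: int, fs: float, exponent: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power spectral density ~ f^-exponent,
    generated by frequency-domain shaping; RMS equal to ``scale``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def _von_mises_modulation(phase: np.ndarray, mode: str, kappa: float, mu: float) -> np.ndarray:
    """Mean-one intensity modulation g(phi).  Unimodal: von Mises at mu.
    Bimodal: equal mixture at mu and mu + pi (antipodal preferred phases)."""
    if mode == "unimodal":
        return np.exp(kappa * np.cos(phase - mu)) / i0(kappa)
    if mode == "bimodal":
        return 0.5 * (
            np.exp(kappa * np.cos(phase - mu)) + np.exp(kappa * np.cos(phase - mu - np.pi))
        ) / i0(kappa)
    raise ValueError(f"unknown coupling mode {mode!r}")


def coupled_spike_times(
    phase_series: np.ndarray,
    fs: float,
    mode: str,
    kappa: float,
    rate_hz: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    preferred_phase: float = 0.0,
) -> np.ndarray:
    """Inhomogeneous point process whose intensity is a von Mises
    function of an oscillation's phase.

    The modulation has unit circular mean, so when the phase sweeps the
    circle uniformly the expected count is ~ rate_hz x duration.
    kappa=0 degenerates to a homogeneous Poisson process.  Sampled by
    thinning; returns sorted times in seconds relative to the start of
    ``phase_series``.
    """
    phase = np.asarray(phase_series, dtype=float)
    if phase.ndim != 1:
        raise ValueError("phase_series must be 1-D")
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase_series must be finite")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if rate_hz < 0:
        raise ValueError("rate_hz must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    duration = phase.size / fs
    if rate_hz == 0 or phase.size == 0:
        return np.empty(0)
    lam_max = rate_hz * float(np.exp(kappa) / i0(kappa))
    n_cand = rng.poisson(lam_max * duration)
    if n_cand == 0:
        return np.empty(0)
    t_cand = rng.uniform(0.0, duration, n_cand)
    idx = np.minimum((t_cand * fs).astype(int), phase.size - 1)
    g = _von_mises_modulation(phase[idx], mode, kappa, preferred_phase)
    keep = rng.uniform(0.0, 1.0, n_cand) < (rate_hz * g) / lam_max
    return np.sort(t_cand[keep])


def pds_burst(
    n_neurons: int,
    jitter_ms: float,
    fs: float,
    spike_waveform: np.ndarray | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    return_onsets: bool = False,
):
    """Summated population burst: ``n_neurons`` spike waveforms with
    Gaussian-jittered onsets (SD ``jitter_ms``).

    With zero jitter the output is exactly n_neurons x the waveform
    (onsets are rounded to integer samples).  Growing jitter spreads
    the onsets, which broadens the spectral content of the summed
    potential — the generative model of broadband high-frequency LFP.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if spike_waveform is None:
        spike_waveform = biphasic_spike(fs)
    wf = np.asarray(spike_waveform, dtype=float)
    offsets = np.round(rng.normal(0.0, jitter_ms * 1e-3, n_neurons) * fs).astype(int)
    pad = int(np.ceil(4 * jitter_ms * 1e-3 * fs)) + 1
    n = 2 * pad + wf.size
    out = np.zeros(n)
    center = pad
    for off in offsets:
        start = int(np.clip(center + off, 0, n - wf.size))
        out[start : start + wf.size] += wf
    if return_onsets:
        return out, (offsets + center) / fs
    return out


def _ricker(sigma_s: float, fs: float, amp_v: float) -> np.ndarray:
    """Mexican-hat transient standing in for the slow epileptiform
    discharge deflection (negative-peak convention)."""
    half = int(np.ceil(4 * sigma_s * fs))
    t = np.arange(-half, half + 1) / fs
    u = (t / sigma_s) ** 2
    return -amp_v * (1 - u) * np.exp(-u / 2)


def _add_at(trace: np.ndarray, waveform: np.ndarray, center_idx: int) -> None:
    """Add waveform centered at center_idx, clipping at trace edges."""
    half = waveform.size // 2
    lo = center_idx - half
    hi = lo + waveform.size
    wlo = max(0, -lo)
    whi = waveform.size - max(0, hi - trace.size)
    if whi <= wlo:
        return
    trace[max(0, lo) : max(0, lo) + (whi - wlo)] += waveform[wlo:whi]


def simulate_recording(config: SimConfig) -> tuple[SyntheticRecording, GroundTruth]:
    """Generate a synthetic seizure with full ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs_micro
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    # --- dominant rhythm oscillator: frequency drifts up until recruitment
    f_inst = cfg.gamma_freq_hz + cfg.gamma_drift_hz_per_s * np.clip(
        t - cfg.onset_s, 0.0, max(cfg.wavefront_time_s - cfg.onset_s, 0.0)
    )
    theta = 2 * np.pi * np.cumsum(f_inst) / fs

    # --- seizure-wide rhythmic discharge times: riding the peaks of a
    # continuous low-frequency ictal rhythm (rhythmic-onset morphology)
    if cfg.discharge_rate_hz > 0:
        period = 1.0 / cfg.discharge_rate_hz
        base = np.arange(cfg.onset_s, cfg.duration_s - 2.0, period)
        discharge_times = np.sort(base + rng.normal(0.0, 0.008, base.size))
        discharge_times = discharge_times[
            (discharge_times > cfg.onset_s - 0.5) & (discharge_times < cfg.duration_s - 2.0)
        ]
        # the rhythm itself: tapered cosine peaking at the base grid times
        rhythm = np.zeros(n)
        r0 = cfg.onset_s - 0.5 * period
        r1 = min(float(base[-1]) + 0.5 * period, cfg.duration_s)
        i0r, i1r = int(r0 * fs), int(r1 * fs)
        tt = t[i0r:i1r]
        taper = np.minimum(1.0, np.minimum(tt - r0, r1 - tt) / 1.0)
        rhythm[i0r:i1r] = (
            cfg.rhythm_amp_v * np.clip(taper, 0.0, 1.0)
            * np.cos(2 * np.pi * cfg.discharge_rate_hz * (tt - cfg.onset_s))
        )
    else:
        discharge_times = np.empty(0)
        rhythm = np.zeros(n)

    recruit = cfg.wavefront_time_s + cfg.wavefront_delay_s * np.arange(cfg.n_micro_channels)
    if np.any(recruit >= cfg.duration_s):
        raise ValueError("wavefront does not cross all micro channels inside the recording")

    wf_spike = biphasic_spike(fs, amp_v=cfg.spike_amp_v)
    slow_wave = _ricker(0.04, fs, cfg.slow_wave_amp_v)
    burst_half = int(np.ceil(3 * cfg.burst_sigma_s * fs))
    osc_period = int(np.ceil(fs / cfg.gamma_freq_hz))

    micro = np.empty((cfg.n_micro_channels, n))
    spikes: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    rows: list[tuple[float, int, str]] = []

    for ch in range(cfg.n_micro_channels):
        trace = rhythm + shaped_noise(n, fs, cfg.background_exponent, cfg.noise_scale, rng)
        ch_spikes: list[np.ndarray] = []
        ch_labels: list[np.ndarray] = []
        if discharge_times.size:
            # background multiunit firing and the wavefront tonic surge
            base_times = np.sort(
                rng.uniform(0.0, cfg.duration_s, rng.poisson(cfg.baseline_rate_hz * cfg.duration_s))
            )
            ch_spikes.append(base_times)
            ch_labels.append(np.full(base_times.size, "baseline"))
            # waxing/waning tonic surge peaked at wavefront passage
            sd = cfg.tonic_duration_s / 3.0
            n_tonic = rng.poisson(cfg.tonic_rate_hz * cfg.tonic_duration_s)
            tonic = recruit[ch] + rng.normal(0.0, sd, n_tonic)
            tonic = np.sort(tonic[np.abs(tonic - recruit[ch]) < 1.5 * cfg.tonic_duration_s])
            ch_spikes.append(tonic)
            ch_labels.append(np.full(tonic.size, "tonic"))

        for t0 in discharge_times:
            epoch = "pre" if t0 < recruit[ch] else "post"
            rows.append((float(t0), ch, epoch))
            i0_ = int(round(t0 * fs))
            _add_at(trace, slow_wave, i0_)
            lo = max(0, i0_ - burst_half)
            hi = min(n, i0_ + burst_half)
            if epoch == "pre":
                # narrowband gamma burst: Gaussian-windowed dominant rhythm
                env = np.exp(-0.5 * ((t[lo:hi] - t0) / cfg.burst_sigma_s) ** 2)
                trace[lo:hi] += cfg.gamma_amp_v * env * np.cos(theta[lo:hi])
                ev = coupled_spike_times(
                    theta[lo:hi], fs, "bimodal", cfg.coupling_kappa_pre,
                    cfg.pre_spike_rate_hz, rng=rng,
                ) + lo / fs
                center = t0
                lab = "pre_bimodal"
            else:
                # PDS: snap the burst center to the nearest rhythm peak so
                # the LFP transient and the coupled firing share a phase
                w0 = max(0, i0_ - osc_period)
                w1 = min(n, i0_ + osc_period + 1)
                i_pk = w0 + int(np.argmax(np.cos(theta[w0:w1])))
                burst = pds_burst(
                    cfg.n_neurons_per_channel, cfg.pds_jitter_ms, fs, wf_spike, rng=rng
                )
                _add_at(trace, burst, i_pk)
                ev = coupled_spike_times(
                    theta[lo:hi], fs, "unimodal", cfg.coupling_kappa_post,
                    cfg.post_spike_rate_hz, rng=rng,
                ) + lo / fs
                center = i_pk / fs
                lab = "post_unimodal"
            # burst firing rides the discharge envelope: thin the coupled
            # train with a Gaussian window so the rate peaks at the discharge
            keep = rng.uniform(0.0, 1.0, ev.size) < np.exp(
                -0.5 * ((ev - center) / cfg.burst_sigma_s) ** 2
            )
            ev = ev[keep]
            ch_spikes.append(ev)
            ch_labels.append(np.full(ev.size, lab))

        if ch_spikes:
            all_ev = np.concatenate(ch_spikes)
            all_lab = np.concatenate(ch_labels)
            order = np.argsort(all_ev, kind="stable")
            all_ev, all_lab = all_ev[order], all_lab[order]
        else:
            all_ev, all_lab = np.empty(0), np.empty(0, dtype="U12")
        spikes[ch] = all_ev
        labels[ch] = all_lab
        for ev in all_ev:
            _add_at(trace, wf_spike, int(round(ev * fs)))
        micro[ch] = trace

    # --- macro channels: mixed micro neighborhoods (core) or independent
    # penumbral sources that carry narrowband gamma throughout
    n_core = (cfg.n_macro_channels + 1) // 2
    domains = ["core"] * n_core + ["penumbra"] * (cfg.n_macro_channels - n_core)
    macro_hi = np.empty((cfg.n_macro_channels, n))
    for m in range(cfg.n_macro_channels):
        gain = rng.uniform(0.85, 1.15)
        noise = shaped_noise(n, fs, cfg.background_exponent, cfg.noise_scale, rng)
        if domains[m] == "core":
            w = rng.uniform(0.5, 1.5, cfg.n_micro_channels)
            w /= w.sum()
            macro_hi[m] = gain * (w @ micro) + noise
        else:
            src = gain * rhythm.copy()
            amp = cfg.gamma_amp_v * cfg.penumbra_gain * gain
            for t0 in discharge_times:
                i0_ = int(round(t0 * fs))
                _add_at(src, gain * slow_wave, i0_)
                lo = max(0, i0_ - burst_half)
                hi = min(n, i0_ + burst_half)
                env = np.exp(-0.5 * ((t[lo:hi] - t0) / cfg.burst_sigma_s) ** 2)
                src[lo:hi] += amp * env * np.cos(theta[lo:hi])
            macro_hi[m] = src + noise

    # mirror clinical preprocessing: 4th-order zero-phase low-pass, decimate
    sos = butter(4, 0.48 * cfg.fs_macro, btype="lowpass", fs=fs, output="sos")
    macro_lp = sosfiltfilt(sos, macro_hi, axis=1)
    step = fs / cfg.fs_macro
    if abs(step - round(step)) > 1e-9:
        raise ValueError("fs_micro must be an integer multiple of fs_macro")
    macro = macro_lp[:, :: int(round(step))]

    ds = 30  # dominant-frequency truth stored at fs/30 (100 Hz at default)
    gt = GroundTruth(
        recruitment_time_s=recruit,
        discharges=pd.DataFrame(rows, columns=["time_s", "channel", "epoch"]),
        discharge_times_s=discharge_times,
        spike_times_s=spikes,
        spike_labels=labels,
        macro_channel_domain=domains,
        dominant_freq_truth_hz=f_inst[::ds].copy(),
        dominant_freq_times_s=t[::ds].copy(),
    )
    rec = SyntheticRecording(
        micro=micro,
        fs_micro=fs,
        macro=macro,
        fs_macro=cfg.fs_macro,
        micro_channel_ids=list(range(1, cfg.n_micro_channels + 1)),
        macro_channel_ids=list(range(1, cfg.n_macro_channels + 1)),
    )
    return rec, gt
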