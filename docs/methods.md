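# Methods

`ictalhfo` analyzes multiscale intracranial recordings of rhythmic-onset
focal seizures to distinguish two generators of high-frequency LFP:

* **narrowband gamma** (~40–80 Hz): a true oscillation produced while
  feed-forward inhibition is intact, sculpting population firing into
  periodic windows.  It dominates *pre-recruitment* discharges and the
  spatial *penumbra*;
* **broadband high-frequency activity (BHF, ~70–200+ Hz)**: an aperiodic
  spectral shift produced by summated, temporally jittered population
  spikes during paroxysmal depolarizing shifts (PDS).  It dominates
  *post-recruitment* discharges in the *ictal core*.

Because the human recordings that motivate this analysis are not
publicly available, the package ships a synthetic seizure generator
whose ground truth exercises every analysis stage.

## The synthetic seizure (`synthgen`)

A recording is a set of micro channels (default 8 at 3 kS/s) and macro
channels (default 12 at 500 S/s) over 60 s.  Components:

* **Background**: Gaussian noise with PSD ∝ f⁻ⁿ (default n = 1),
  RMS 10 µV.  Discharge events are 25–35× larger, as on penetrating
  microelectrodes during seizures.
* **Ictal rhythm**: a tapered cosine at the discharge rate (default
  1.5 Hz, 300 µV) spanning the seizure, with one discharge per rhythm
  peak plus a 150 µV sharp transient.  A *continuous* rhythm matters:
  with isolated transients only, the 1–25 Hz analytic phase dwells at a
  fixed value between discharges, and that dwell-phase baseline vector
  cancels the burst vector in phase-locked measures.  A continuous
  rhythm sweeps phase uniformly and is the defining morphology of the
  rhythmic-onset seizures this analysis targets.
* **Dominant-frequency drift**: a global oscillator starts at 55 Hz and
  rises 0.3 Hz/s until recruitment (~61 Hz), then holds — the
  "dominant frequency increases until the point of recruitment"
  phenomenology.
* **Wavefront**: recruitment reaches micro channel *i* at
  30 s + 0.1 s·i.  Passage is marked by a waxing/waning tonic multiunit
  surge (Gaussian intensity profile, 500 Hz × 2.5 s, peaked at
  passage), the dominant firing event of the simulation; the
  recruitment-time estimator's per-channel rate argmax is then
  well-defined.
* **Pre-recruitment discharges**: Gaussian-windowed (σ = 40 ms) bursts
  of the dominant oscillator, 250 µV, plus multiunit spikes drawn from
  a **bimodal** von Mises intensity on the oscillator phase
  (κ = 2, antipodal modes, burst rate 900 Hz thinned by the discharge
  envelope).
* **Post-recruitment discharges**: a PDS — 100 spike waveforms with
  onsets jittered at 2 ms SD, summed — snapped to the nearest
  oscillator peak, plus **unimodal** von Mises spikes (κ = 2, 150 Hz).
  At 2 ms jitter the coherent part of the summated potential spans
  ~70–200 Hz (e^{−(2πfσ)²/2} roll-off), i.e. exactly the BHF band; at
  5 ms it collapses below 70 Hz and post discharges would carry *less*
  absolute 50–200 Hz amplitude than the gamma bursts.  The asymmetric
  burst rates mirror the observed measurement: detected event rates
  during PDS are limited by waveform overlap and collapse, while
  penumbral bursts remain individually resolvable — this is what makes
  normalized firing rate and normalized BHF amplitude anticorrelated
  across discharges.
* **Macro channels**: half are *core* (a weighted mix of the micro
  channels, low-pass filtered 4th-order Butterworth and decimated to
  500 S/s) and half *penumbra* (narrowband gamma discharges throughout
  the seizure, never PDS, at the same amplitude as pre-recruitment
  core gamma — the penumbral amplitude is exposed as a free gain).

Everything is drawn from one seeded generator; a fixed seed gives
bit-identical output.

### What the generator does not emulate

Electrode drift and artifacts; spatial geometry beyond a linear channel
ordering; single-unit identity (multiunits only, as in the analysis it
feeds); chloride dynamics or any biophysical membrane model; and
seizure-to-seizure heterogeneity (one stereotyped seizure per seed).  A
green test on this world establishes that the *analysis chain* recovers
the stated structure, not that the structure exhausts real seizures.

## Spectral analysis (`spectral`)

Scaleograms use 5-cycle Morlet wavelets on 107 log-spaced bins (1–200 Hz
for macro, 1–850 Hz for micro data), computed by frequency-domain
multiplication with analytic Gaussian kernels.  The amplitude
convention is envelope-like (L1): a unit sinusoid yields magnitude ≈ 1
at its bin.  Under this convention magnitude is linear in signal gain
and tones localize exactly; consequences worth knowing: after the 1/f
normalization (each row divided by S(f) = f⁻¹, i.e. multiplied by f)
equal-amplitude tones scale ∝ f, and the normalized magnitude of white
noise grows ∝ f^{3/2}.  No single wavelet normalization makes the
normalized spectrum simultaneously flat for equal tones and slope-one
for white noise; the tests assert the analytic response of the
documented convention.

The dominant frequency is the per-time-bin argmax of the (normalized)
scaleogram, smoothed by a moving average of round(fs/8) samples
(125 ms) and snapped back to the grid.  Wavelet edge regions (half a
wavelet length) are flagged per frequency, not dropped.  Band
envelopes are |analytic signal| of zero-phase 4th-order Butterworth
band-passes.

## Detection (`detect`)

* **Multiunit events**: zero-phase band-pass 300–3000 Hz (upper edge
  fs/2 − 100 at lower rates, 300–1400 Hz at 3 kS/s), then negative-going
  peaks above 3.5 robust standard deviations,
  σ̂ = median(|x|)/(2/3).  The robust-estimator reading matters: a
  threshold of 3.5·(2/3)·median(|x|) ≈ 1.6 σ floods pure noise with
  crossings.  Thresholding on the filtered signal makes detection
  invariant to amplitude rescaling.
* **Macro discharges**: smoothed (10 ms) 50–200 Hz power envelope →
  local maxima above mean + 1 SD with 50 ms separation; candidates are
  clustered (k-means, k = 7) on z-scored (peak amplitude,
  inter-detection interval) and clusters are dropped when their median
  amplitude is < 50% of the global median or their median interval
  deviates > 3 MADs; a candidate-level amplitude floor applies the same
  50% rule per detection.  A burst-structure gate (99.9th-percentile /
  median power ≥ 20) returns nothing on stationary noise, where a
  purely relative threshold would otherwise always fire.  A
  `manual_keep` mask supports human review.
* **MEA discharges**: per-channel firing rate and high-gamma envelope
  are smoothed with a 10 ms-SD Gaussian, min–max normalized, averaged
  over channels; maxima above 1 SD in *each* modality are matched
  within 50 ms (stronger peak wins ties; unmatched maxima are
  discarded).
* **Recruitment time**: mean over channels of the argmax of the
  500 ms-SD smoothed rate ("500 ms width" read as the SD, consistent
  with the 10 ms kernel being specified as an SD; earliest argmax wins
  ties; the mean-of-argmax rather than argmax-of-mean reading is the
  default).
* **Balancing**: discharges are labeled pre/post against the
  recruitment time and the larger epoch is randomly subsampled (fixed
  seed) to the smaller's size.
* **Recruited-unit call**: a contiguous ≥ 2 s interval with rate ≥ 5×
  the pre-seizure baseline mean, followed by firing whose resultant
  length exceeds the 95th percentile of a phase-resampling null.

## Coupling (`coupling`)

Phases come from the analytic signal of a zero-phase 96th-order FIR
band-pass at f₀ ± 5 Hz around the dominant frequency, read at the
nearest sample to each event (cosine convention: 0 at the band-passed
peak).  The two-sample Kuiper statistic is V = D⁺ + D⁻ with
D⁺ = sup(F_a − F_b), D⁻ = sup(F_b − F_a) over the pooled sample — a
rank statistic, invariant under common rotations (the subtraction
variant that sometimes appears in print is available as
`as_printed=True`; permutation calibration makes either a valid test).
The permutation test pools both samples, draws two disjoint m-sized
subsets (default m = 2000) per permutation, and reports
p = (1 + #{V_null ≥ V_obs}) / (1 + n_perm), so p is never zero and the
test is exactly calibrated when the sample sizes equal m.  The
bimodal-vs-unimodal dispersion contrast angle-doubles the bimodal
sample (folding antipodal modes) and applies the circular-dispersion F
ratio F = [(n₁−R₁)/(n₁−1)]/[(n₂−R₂)/(n₂−1)] ~ F(n₁−1, n₂−1),
two-sided; the approximation is intended for reasonably concentrated
samples (r̄ ≳ 0.5).

## Classification (`classify`)

Phase-locked band power is |mean_t a(t)·e^{iφ(t)}| with a(t) the
high-band envelope (narrowband gamma 30–70 Hz, BHF 95–200 Hz, or
dominant f₀ ± 5 Hz) and φ(t) the 1–25 Hz ictal-rhythm phase — the
vector-strength formulation of the phase-locked high-gamma biomarker
(an envelope perfectly cosine-modulated at the rhythm with mean
amplitude A scores A/2; an unmodulated one scores ~0).  Channels are
labeled by a two-component univariate Gaussian mixture on the
post-recruitment phase-locked BHF values: EM with k-means++
initialization (fixed seed), tolerance 1e-8 on the log-likelihood, max
500 iterations, variance floor 1e-10·var; the higher-mean component is
the core.  Labels are invariant under positive rescaling of the values.
The GMM is fit per seizure.

## Complexity (`complexity`)

Each discharge is summarized on a fixed window centered at the peak:
296 samples at 3 kS/s (~99 ms) on micro, 98 samples at 500 S/s
(~196 ms) on macro.  Windows are reflection-padded before the Morlet
transform and the magnitude averaged over the original samples, then
1/f-normalized and distribution-normalized.

* differential entropy h(V) = −(1/n)·Σ p(v) log₂ p(v), histogram over
  32 equal-width bins spanning the window's range (the 1/n factor is a
  constant within an electrode class and is kept as conventionally
  printed; it cannot change within-class comparisons);
* spectral entropy h(S) = −Σ p log₂ p in bits, maximal at log₂(n_bins)
  for a flat spectrum (5.64 bits for the 50-bin macro grid, 6.74 for
  the 107-bin micro grid);
* spectral mode: argmax frequency of the metric-band spectrum;
* fast-ripple index (micro): proportion of the normalized 100–800 Hz
  spectrum above 250 Hz; ripple index (macro): proportion of the
  1–250 Hz spectrum between 80 and 200 Hz.  The macro grid is built
  endpoint-exclusive (geomspace(1, 250, 51)[:-1]) because 250 Hz is the
  macro Nyquist.

A caution learned from the generator: on the 100–800 Hz metric band a
pure ~60 Hz oscillation contributes nothing, so what a "narrowband"
discharge scores there is decided by its harmonics and any noise floor
— and a noise floor is itself near-maximal entropy under f-weighting.
Mechanism comparisons (summated jittered bursts vs narrowband bursts)
are therefore made against harmonic-rich, noise-free gamma templates.
Relatedly, a zero-jitter summated burst is impulse-like and already
spectrally near-flat; jitter *broadens relative to periodic or
narrowband firing*, not relative to an impulse.

## Statistics (`stats`)

The epoch contrast on a per-discharge metric is a linear mixed model,
metric ~ 1 + epoch with random intercept and slope per seizure, fit by
ML via statsmodels MixedLM (singular random-slope fits fall back,
flagged, to random intercepts).  Wald z inference on the fixed effect
is reliable here only when the between-seizure slope variance is small
relative to the within-seizure error — with three seizures a slope SD
of 0.2 (noise SD 1) already inflates the type-I rate to ~0.20, which
is a property of the inference, not the implementation.

Bayes factors come from the BIC identity
BF = exp(ΔBIC/2) = ((SS_error + SS_response)/SS_error)^{n/2},
computed in log space, with k = 2 parameters and the direction
convention exactly as conventionally printed (SS_response = 0 ⇒ BF = 1).
SS_response is defined operationally as the reduction in residual sum
of squares from the intercept-only fit to the epoch fit, residuals
taken against the marginal (fixed-effects) predictions.

Discharge-level Pearson correlations (normalized firing-rate peak vs
normalized BHF peak, overall and within epoch) use all detected
discharges by default; a balanced-only switch is the alternative.

## Pipeline and I/O

Stage order: simulate → macro discharge detection and dominant
frequency (median of the dominant-frequency series at discharge times,
on the channel with the strongest 50–200 Hz envelope) → multiunit
detection and recruitment → MEA discharge detection, labeling,
balancing → coupling tests → channel classification → per-discharge
complexity → correlations.  All stage seeds derive from one run seed
and are recorded in the run log; the on-disk outputs are bit-identical
across reruns of the same configuration (timing lives only in
`runlog.json`).  The recording container is HDF5 (`/micro`, `/macro`,
`/ground_truth`; volts/seconds/Hz); macro data above 500 S/s are
low-pass filtered (4th-order Butterworth) and decimated on ingest.
With a single simulated seizure the mixed model is skipped and noted in
the summary; `stats.fit_epoch_mixed_model` is exercised on multi-seizure
tables.

## Known limitations

* The generator produces one stereotyped seizure archetype; rate- and
  amplitude-regime conclusions should not be read as clinical claims.
* Nearest-sample phase read-out quantizes phases at low sampling rates
  (a 60 Hz rhythm at 500 S/s has ~8 samples per cycle).
* The concentration F-test is a large-concentration approximation; for
  nearly uniform samples use the permutation Kuiper test instead.
* The dominant-frequency estimate rides on the f-weighted spectrum and
  is biased upward by roughly one to two grid bins (~5%) for narrowband
  signals.
* Patient-level headline numbers from the motivating recordings
  (specific r, t, percentage splits) are not reproducible from
  synthetic data and are not targets of this package.
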