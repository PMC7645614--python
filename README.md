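# ictalhfo

Mechanistic classification of ictal high-frequency oscillations (HFOs)
in rhythmic-onset focal seizures, for electrophysiologists and epilepsy
researchers working with combined micro- and macroelectrode recordings.

High-frequency LFP during seizures arises from two distinct generators
with opposite clinical meaning:

* **narrowband gamma** (~40–80 Hz) — a true oscillation sculpted by
  intact feed-forward inhibition.  It marks tissue *receiving* the
  seizure (the penumbra / pre-recruitment epoch) and can appear far
  from the seizure focus;
* **broadband high-frequency activity** (BHF, ~70–200 Hz) — an
  aperiodic spectral shift from summated, temporally jittered
  population spikes during paroxysmal depolarizing shifts.  It marks
  *recruited* tissue (the ictal core / post-recruitment epoch).

The package implements the full analysis chain that separates them:

* 5-cycle Morlet scaleograms on 107 log-spaced bins, normalized by the
  theoretical background spectrum S(f) = f⁻¹; dominant-frequency
  tracking (argmax smoothed over fs/8 samples);
* multiunit detection (300–3000 Hz band, 3.5 robust-SD threshold with
  σ̂ = median|x|/(2/3)), firing rates by Gaussian-kernel convolution,
  and recruitment time as the mean over channels of the 500 ms-kernel
  rate argmax;
* discharge detection on macroelectrodes (50–200 Hz power threshold +
  k-means cleanup, k = 7) and microelectrode arrays (cross-referenced
  firing-rate / high-gamma maxima, 50 ms matching), with balanced
  pre/post retention;
* spike–LFP phase coupling at the dominant frequency (96th-order FIR,
  f₀ ± 5 Hz) and a permutation Kuiper test
  (V = D⁺ + D⁻, pooled m-subset null, p = (1 + #{V₀ ≥ V})/(1 + N));
  the angle-doubled two-sample concentration F-test for the
  bimodal→unimodal coupling transition;
* phase-locked band power |⟨a(t)·e^{iφ(t)}⟩| (high-band envelope
  against the 1–25 Hz ictal-rhythm phase) and core/penumbra labeling by
  a 2-component Gaussian mixture on post-recruitment phase-locked BHF;
* per-discharge complexity: differential entropy
  h(V) = −(1/n)Σp log₂p, spectral entropy h(S) = −Σp log₂p
  (maximum log₂ n_bins), spectral mode, fast-ripple (>250 Hz) and
  ripple (80–200 Hz) indices;
* mixed-model epoch contrasts (metric ~ 1 + epoch + (1 + epoch |
  seizure)) with BIC Bayes factors
  BF = ((SS_error + SS_response)/SS_error)^{n/2}, and discharge-level
  correlations.

Because the motivating human recordings are not public, a synthetic
seizure generator (`ictalhfo.synthgen`) produces recordings with known
ground truth — propagating wavefront, drifting dominant frequency,
bimodally coupled gamma bursts, jittered PDS bursts, core and penumbral
macro channels — so every stage is testable end to end.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

```bash
ictalhfo run-all --seed 7 --out-dir demo_out
```

simulates a 60 s default seizure and runs every stage (~4 s on one
CPU).  `demo_out/summary.json` then contains, among others:

```
"spectral":   {"dominant_freq_hz": 63.35, "n_macro_discharges": 72}
"detect":     {"n_mea_discharges": 72, "n_pre": 31, "n_post": 41,
               "recruitment_time_s": 30.26}
"couple":     {"kuiper_p": 0.0005, "concentration_p": 0.0}
"classify":   {"label_accuracy": 1.0, "n_core": 6}
"complexity": {"median_spectral_entropy_bits_pre": 6.44,
               "median_spectral_entropy_bits_post": 6.50}
"stats":      {"r_mua_vs_bhf_all": -0.80}
```

Reading these numbers: the seizure's dominant rhythm sits at ~63 Hz;
all 72 rhythmic discharges are recovered and split 31 pre / 41 post
around the estimated wavefront passage at 30.26 s (truth: 30.35 s).
The spike-phase distribution changes significantly between epochs
(permutation Kuiper p = 0.0005, the resolution floor at 2000
permutations), all 12 macro channels are labeled correctly
core/penumbra from post-recruitment phase-locked BHF, post-recruitment
discharges are spectrally more complex, and normalized firing-rate and
BHF amplitudes are anticorrelated across discharges (r = −0.80) — the
two-axis signature separating the two HFO mechanisms.

Per-discharge tables (`discharges.csv`, `complexity.csv`), channel
labels (`channel_labels.csv`), the dominant-frequency series, and the
coupling test results are written alongside.  The same stages are
available individually (`ictalhfo simulate | detect | couple |
classify | complexity | stats`) and as library functions.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — simulating a
default synthetic seizure from the given seed and executing the full
analysis pipeline — and writes the results manifest to `--out`.
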