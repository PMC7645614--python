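"""Multiunit and discharge detection, recruitment time, balancing."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, sosfiltfilt

from ictalhfo.detect import (
    classify_unit_recruited,
    detect_discharges_macro,
    detect_discharges_mea,
    detect_mua,
    firing_rate,
    label_and_balance,
    recruitment_time,
)
from ictalhfo.synthgen import biphasic_spike, shaped_noise

FS = 3000.0


def _threshold(signal, fs=FS):
    sos = butter(4, (300.0, fs / 2 - 100.0), btype="bandpass", fs=fs, output="sos")
    xf = sosfiltfilt(sos, signal)
    return 3.5 * (2.0 / 3.0) * np.median(np.abs(xf)), xf


class TestDetectMua:
    def test_zero_signal_has_no_events(self):
        assert detect_mua(np.zeros(3000), FS).size == 0

    def test_injected_spikes_recovered_exactly(self):
        """Oracle: direct enumeration of threshold crossings.  All 20
        spikes at 10x threshold are recovered within 0.5 ms; detection
        equals an independent threshold-crossing scan; false positives
        stay within the Gaussian peak-tail expectation."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(20 * FS)) * 1e-5
        thr, _ = _threshold(x)
        wf = biphasic_spike(FS)
        wf = wf * (10 * thr / np.abs(wf).max())
        true_times = (np.arange(20) + 0.5) * 0.9
        for t in true_times:
            i = int(t * FS)
            x[i : i + wf.size] += wf
        ev = detect_mua(x, FS)
        # every injected spike recovered at its trough
        matched = [np.min(np.abs(ev - (t + np.argmin(wf) / FS))) for t in true_times]
        assert max(matched) <= 0.5e-3
        # detection equals the independent enumeration oracle
        thr2, xf = _threshold(x)
        neg = -xf
        refr = max(1, int(round(5e-4 * FS)))
        brute = []
        last = -refr
        for i in range(1, neg.size - 1):
            if neg[i] > thr2 and neg[i] >= neg[i - 1] and neg[i] > neg[i + 1]:
                if i - last >= refr and (not brute or neg[i] > 0):
                    brute.append(i)
                    last = i
        # the oracle reproduces find_peaks' plateau/refractory handling
        # only approximately; compare as sets within one sample
        brute_t = np.array(brute) / FS
        assert all(np.min(np.abs(brute_t - e)) <= 1.5 / FS for e in ev)
        # false positives bounded by the one-sided Gaussian tail estimate
        fp = sum(np.min(np.abs((true_times + np.argmin(wf) / FS) - e)) > 0.5e-3 for e in ev)
        from scipy.stats import norm
        sigma_hat = np.median(np.abs(xf)) / (2.0 / 3.0)
        tail = norm.sf(3.5 * sigma_hat / xf.std())
        assert fp <= 3 * tail * xf.size + 5

    def test_subthreshold_spike_not_detected(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(5 * FS)) * 1e-5
        thr, _ = _threshold(x)
        wf = biphasic_spike(FS)
        x_with = x.copy()
        i = int(2.5 * FS)
        x_with[i : i + wf.size] += wf * (0.9 * thr / np.abs(wf).max())
        base = detect_mua(x, FS)
        withspike = detect_mua(x_with, FS)
        near = np.abs(withspike - 2.5) < 2e-3
        assert not near.any()
        assert withspike.size <= base.size + 1

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(10 * FS)) * 1e-5
        assert np.array_equal(detect_mua(x, FS), detect_mua(100.0 * x, FS))

    def test_fs_too_low_errors(self):
        with pytest.raises(ValueError, match="too low"):
            detect_mua(np.zeros(100), 700.0)


class TestFiringRate:
    def test_empty_train_is_zero(self):
        _, rate = firing_rate(np.empty(0), 0.01, 1000.0, duration_s=1.0)
        assert np.all(rate == 0)

    def test_single_event_integrates_to_one(self):
        times, rate = firing_rate(np.array([0.5]), 0.01, 1000.0, duration_s=1.0)
        assert np.trapezoid(rate, times) == pytest.approx(1.0, abs=1e-3)

    def test_poisson_train_recovers_rate(self):
        """Law of large numbers; oracle = event count / duration."""
        rng = np.random.default_rng(3)
        ev = np.sort(rng.uniform(0, 100, rng.poisson(50 * 100)))
        times, rate = firing_rate(ev, 0.01, 1000.0, duration_s=100.0)
        sl = slice(1000, -1000)
        assert rate[sl].mean() == pytest.approx(ev.size / 100.0, rel=0.02)
        assert abs(rate[sl].mean() - 50.0) < 3.0

    def test_rate_integral_matches_count(self):
        rng = np.random.default_rng(4)
        ev = np.sort(rng.uniform(1, 9, 200))
        times, rate = firing_rate(ev, 0.02, 500.0, duration_s=10.0)
        assert np.trapezoid(rate, times) == pytest.approx(200, rel=0.02)


def _burst_train(fs, n_bursts=20, spacing=1.0, amp=1e-4, freq=80.0, t0=1.0):
    dur = t0 * 2 + n_bursts * spacing
    n = int(dur * fs)
    t = np.arange(n) / fs
    x = np.zeros(n)
    centers = t0 + np.arange(n_bursts) * spacing
    for c in centers:
        env = np.exp(-0.5 * ((t - c) / 0.03) ** 2)
        x += amp * env * np.cos(2 * np.pi * freq * t)
    return x, centers, dur


class TestDetectDischargesMacro:
    def test_regular_bursts_all_retained(self):
        fs = 500.0
        x, centers, _ = _burst_train(fs)
        rng = np.random.default_rng(5)
        x += shaped_noise(x.size, fs, 1.0, 1e-6, rng)
        times = detect_discharges_macro(x, fs)
        assert times.size == 20
        assert max(np.min(np.abs(times - c)) for c in centers) < 0.02

    def test_flat_noise_yields_nothing_big(self):
        fs = 500.0
        rng = np.random.default_rng(6)
        x = shaped_noise(int(30 * fs), fs, 0.0, 1e-6, rng)
        # pure noise: candidates are spurious threshold crossings only;
        # nothing resembling a discharge train should survive in number
        times = detect_discharges_macro(x, fs)
        assert times.size < 60  # no burst structure -> sparse noise peaks

    def test_low_amplitude_irregular_artifacts_removed(self):
        """Labeled fixture: 20 true bursts + 5 low-amplitude artifacts at
        irregular spacing; the artifact cluster must be dropped while
        >= 18/20 true bursts survive."""
        fs = 500.0
        x, centers, dur = _burst_train(fs)
        t = np.arange(x.size) / fs
        art_times = np.array([2.37, 5.37, 9.37, 13.37, 17.37])  # >= 0.3 s from bursts
        for c in art_times:
            env = np.exp(-0.5 * ((t - c) / 0.03) ** 2)
            x += (1e-4 / 3.0) * env * np.cos(2 * np.pi * 80.0 * t)
        rng = np.random.default_rng(7)
        x += shaped_noise(x.size, fs, 1.0, 1e-6, rng)
        times = detect_discharges_macro(x, fs)
        true_kept = sum(np.min(np.abs(times - c)) < 0.02 for c in centers)
        art_kept = sum(np.min(np.abs(times - c)) < 0.02 for c in art_times)
        assert true_kept >= 18
        assert art_kept == 0

    def test_few_candidates_skip_clustering_with_warning(self):
        fs = 500.0
        x, _, _ = _burst_train(fs, n_bursts=3, spacing=2.0)
        rng = np.random.default_rng(8)
        x += shaped_noise(x.size, fs, 1.0, 1e-7, rng)
        with pytest.warns(UserWarning, match="skipping k-means"):
            times = detect_discharges_macro(x, fs)
        assert times.size == 3


class TestDetectDischargesMea:
    def _impulse(self, n, fs, at, width=0.01):
        t = np.arange(n) / fs
        out = np.zeros(n)
        for a in np.atleast_1d(at):
            out += np.exp(-0.5 * ((t - a) / width) ** 2)
        return out

    def test_coincident_peaks_yield_one_discharge(self):
        fs = 1000.0
        n = int(5 * fs)
        rate = self._impulse(n, fs, 1.0)
        bhf = self._impulse(n, fs, 1.0)
        out = detect_discharges_mea(rate, bhf, fs)
        assert len(out) == 1
        assert out["time_s"].iloc[0] == pytest.approx(1.0, abs=0.005)

    def test_unmatched_bhf_peak_discarded(self):
        fs = 1000.0
        n = int(5 * fs)
        rate = self._impulse(n, fs, 1.0)
        bhf = self._impulse(n, fs, [1.0, 3.0])
        out = detect_discharges_mea(rate, bhf, fs)
        assert len(out) == 1

    def test_synthetic_seizure_recall_and_precision(self, seizure, detection):
        _, gt = seizure
        mea = detection["mea"]
        truth = gt.discharge_times_s
        recall = np.mean(
            [np.any(np.abs(mea["time_s"].to_numpy() - t) <= 0.025) for t in truth]
        )
        precision = np.mean(
            [np.any(np.abs(truth - t) <= 0.025) for t in mea["time_s"]]
        )
        assert recall >= 0.90
        assert precision >= 0.90


class TestRecruitmentTime:
    def test_single_tonic_burst(self):
        rng = np.random.default_rng(9)
        ev = np.sort(10.0 + rng.normal(0, 0.5, 500))
        assert recruitment_time([ev], duration_s=20.0) == pytest.approx(10.0, abs=0.25)

    def test_mean_of_channel_argmaxes(self):
        rng = np.random.default_rng(10)
        trains = [np.sort(c + rng.normal(0, 0.2, 400)) for c in (9.0, 10.0, 11.0)]
        assert recruitment_time(trains, duration_s=20.0) == pytest.approx(10.0, abs=0.15)

    def test_synthetic_recovery_within_300ms(self, seizure, detection):
        _, gt = seizure
        assert abs(detection["recruitment_time"] - gt.recruitment_time_s.mean()) <= 0.3

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        ev = np.sort(5.0 + rng.normal(0, 0.3, 300))
        base = recruitment_time([ev], duration_s=15.0)
        shifted = recruitment_time([ev + 3.0], duration_s=18.0)
        assert shifted - base == pytest.approx(3.0, abs=0.02)

    def test_empty_channel_warned_all_empty_errors(self):
        rng = np.random.default_rng(12)
        ev = np.sort(5.0 + rng.normal(0, 0.3, 300))
        with pytest.warns(UserWarning, match="no multiunit events"):
            recruitment_time([ev, np.empty(0)], duration_s=10.0)
        with pytest.raises(ValueError):
            recruitment_time([np.empty(0)], duration_s=10.0)


class TestLabelAndBalance:
    def test_equal_groups_all_retained(self):
        t = np.concatenate([np.linspace(1, 9, 10), np.linspace(11, 19, 10)])
        out = label_and_balance(t, 10.0, seed=0)
        assert out["retained_after_balancing"].all()
        assert (out["epoch"] == "pre").sum() == 10

    def test_larger_group_subsampled_reproducibly(self):
        t = np.concatenate([np.linspace(1, 9, 30), np.linspace(11, 19, 10)])
        a = label_and_balance(t, 10.0, seed=7)
        b = label_and_balance(t, 10.0, seed=7)
        ra = a[a["retained_after_balancing"]]
        assert (ra["epoch"] == "pre").sum() == (ra["epoch"] == "post").sum() == 10
        pd.testing.assert_frame_equal(a, b)

    def test_boundary_labels(self):
        eps = 1e-9
        out = label_and_balance(np.array([10.0 - eps, 10.0 + eps]), 10.0, seed=0)
        assert list(out["epoch"]) == ["pre", "post"]

    def test_empty_epoch_errors(self):
        with pytest.raises(ValueError, match="both epochs"):
            label_and_balance(np.array([1.0, 2.0]), 10.0, seed=0)


class TestClassifyUnitRecruited:
    FS_PH = 500.0

    def _phase(self, dur=60.0, f=60.0):
        return np.mod(
            2 * np.pi * f * np.arange(int(dur * self.FS_PH)) / self.FS_PH + np.pi,
            2 * np.pi,
        ) - np.pi

    def test_recruited_unit_from_ground_truth(self, seizure):
        rec, gt = seizure
        phase = self._phase()
        # read phases at true event times of a recruited channel; its
        # post-tonic bursts are phase-locked by construction, but here we
        # lock them explicitly by snapping to phase zero
        ev = gt.spike_times_s[0]
        lab = gt.spike_labels[0]
        post = ev[lab == "post_unimodal"]
        period = 1.0 / 60.0
        post_locked = np.round(post / period) * period
        train = np.sort(np.concatenate([ev[lab != "post_unimodal"], post_locked]))
        ok, info = classify_unit_recruited(
            train, phase, self.FS_PH, baseline_window=(0.0, 9.0), seed=0
        )
        assert ok and info["tonic_found"] and info["phase_locked"]

    def test_homogeneous_poisson_not_recruited(self):
        rng = np.random.default_rng(13)
        train = np.sort(rng.uniform(0, 60, 600))
        ok, info = classify_unit_recruited(
            train, self._phase(), self.FS_PH, baseline_window=(0.0, 10.0), seed=0
        )
        assert not ok and not info["tonic_found"]

    def test_tonic_without_locked_bursts_not_recruited(self):
        rng = np.random.default_rng(14)
        base = rng.uniform(0, 60, 300)
        tonic = 30.0 + rng.normal(0, 0.8, 1500)
        flank = rng.uniform(33, 58, 400)  # unlocked, uniform-phase firing
        train = np.sort(np.concatenate([base, tonic, flank]))
        ok, info = classify_unit_recruited(
            train, self._phase(), self.FS_PH, baseline_window=(0.0, 10.0), seed=0
        )
        assert not ok and info["tonic_found"] and not info["phase_locked"]

    def test_missing_baseline_errors(self):
        with pytest.raises(ValueError):
            classify_unit_recruited(
                np.array([1.0]), self._phase(), self.FS_PH, baseline_window=(5.0, 5.0)
            )
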