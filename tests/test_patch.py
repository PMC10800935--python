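"""Tonic-current estimation and sIPSC detection against ground truth."""

import numpy as np
import pytest

from sdsephys import patch, synth
from sdsephys.errors import ValidationError
from sdsephys.trace_io import PatchTrace
from tests.conftest import match_events


def _noise_trace(seed, duration=70.0, fs=10_000.0, sd=5.0, base=-100.0,
                 markers=None):
    rng = np.random.default_rng(seed)
    x = base + rng.standard_normal(int(duration * fs)) * sd
    return PatchTrace(current_pA=x, fs_hz=fs, markers=markers or {})


class TestQc:
    @pytest.mark.parametrize("rs,cm,expected", [
        (0.10, 0.05, True),
        (0.31, 0.0, False),
        (0.0, 0.35, False),
        (0.30, 0.30, True),   # strict ">30%"
    ])
    def test_drift_rule(self, rs, cm, expected):
        trace = PatchTrace(current_pA=np.zeros(100), fs_hz=1000.0,
                           qc={"series_resistance_change_frac": rs,
                               "capacitance_change_frac": cm})
        assert patch.qc_cell(trace) is expected

    def test_missing_qc_metadata_is_error(self):
        trace = PatchTrace(current_pA=np.zeros(100), fs_hz=1000.0)
        with pytest.raises(ValidationError):
            patch.qc_cell(trace)


class TestEpochSampling:
    def test_constant_trace_gives_constant_epoch_means(self):
        trace = PatchTrace(current_pA=np.full(10_000 * 2, -100.0), fs_hz=10_000.0)
        epochs = patch.sample_epoch_means(trace)
        assert np.all(epochs.epoch_means_pA == -100.0)

    def test_thirty_seconds_gives_three_hundred_epochs(self):
        trace = PatchTrace(current_pA=np.zeros(int(30 * 10_000)), fs_hz=10_000.0)
        assert len(patch.sample_epoch_means(trace).epoch_means_pA) == 300

    def test_ramp_epoch_means_equal_ramp_at_epoch_centers(self):
        fs = 10_000.0
        t = np.arange(int(5 * fs)) / fs
        trace = PatchTrace(current_pA=3.0 * t, fs_hz=fs)
        epochs = patch.sample_epoch_means(trace)
        np.testing.assert_allclose(
            epochs.epoch_means_pA, 3.0 * epochs.epoch_times_s, atol=1e-3
        )

    def test_trace_shorter_than_epoch_is_error(self):
        with pytest.raises(ValidationError):
            patch.sample_epoch_means(PatchTrace(current_pA=np.zeros(5), fs_hz=10_000.0))


class TestGaussianFit:
    def test_recovers_mean_of_gaussian_sample(self):
        rng = np.random.default_rng(0)
        mu, _, good = patch.fit_gaussian_holding(rng.normal(-100, 5, 300))
        assert abs(mu - (-100)) < 1.0
        assert good > 0.8

    def test_degenerate_sample_short_circuits(self):
        mu, sd, good = patch.fit_gaussian_holding(np.full(100, -50.0))
        assert (mu, sd) == (-50.0, 0.0)

    def test_bimodal_sample_warns(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(-100, 2, 150), rng.normal(-50, 2, 150)])
        with pytest.warns(patch.GaussianFitWarning):
            patch.fit_gaussian_holding(vals)

    def test_gaussian_fit_mean_close_to_sample_mean_on_pure_noise(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(-80, 4, 500)
        mu, _, _ = patch.fit_gaussian_holding(vals)
        assert abs(mu - vals.mean()) < 0.5

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValidationError):
            patch.fit_gaussian_holding(np.zeros(10))


class TestTonicEstimate:
    def test_noise_free_step_recovered_exactly(self):
        fs = 10_000.0
        x = np.full(int(360 * fs), -120.0)
        x[int(300 * fs):] = -100.0  # bicuculline removes 20 pA inward
        trace = PatchTrace(current_pA=x, fs_hz=fs, markers={"bicuculline": 300.0})
        est = patch.estimate_tonic(trace)
        assert est.tonic_pA == pytest.approx(20.0)

    def test_noisy_shift_recovered_within_uncertainty(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fs = 10_000.0
            x = -120.0 + rng.standard_normal(int(70 * fs)) * 5.0
            x[int(35 * fs):] += 20.0
            trace = PatchTrace(current_pA=x, fs_hz=fs, markers={"bicuculline": 35.0})
            est = patch.estimate_tonic(trace, (5.0, 35.0), (35.0, 65.0))
            errs.append(est.tonic_pA - 20.0)
        assert np.max(np.abs(errs)) < 1.5

    def test_translation_invariance_is_exact(self):
        trace, _ = synth.simulate_patch_trace(synth.PatchSimConfig(seed=5))
        shifted = PatchTrace(current_pA=trace.current_pA + 123.456,
                             fs_hz=trace.fs_hz, markers=trace.markers)
        e1 = patch.estimate_tonic(trace)
        e2 = patch.estimate_tonic(shifted)
        assert e1.tonic_pA == pytest.approx(e2.tonic_pA, abs=1e-6)

    def test_condition_window_overlapping_bicuculline_rejected(self):
        trace, _ = synth.simulate_patch_trace(synth.PatchSimConfig(seed=6))
        with pytest.raises(ValidationError, match="overlap"):
            patch.estimate_tonic(trace, (290.0, 320.0), (320.0, 350.0))

    def test_drug_potentiation_recovered(self, default_patch):
        trace, truth = default_patch
        pre, post = patch.pre_post_tonic(trace)
        pot = patch.drug_tonic_potentiation(pre, post)
        assert abs(pot - (-truth.drug_tonic_shift_pA)) < 2.0
        assert abs(pre.tonic_pA - (-truth.baseline_tonic_pA)) < 2.0


class TestIpscDetection:
    def test_recall_precision_and_tau_against_ground_truth(self):
        cfg = synth.PatchSimConfig(noise_sd_pA=5.0, ipsc_amp_mean_pA=25.0,
                                   ipsc_amp_cv=0.0, ipsc_rate_hz=1.0,
                                   drug_amp_gain=1.0, drug_tau_gain=1.0,
                                   drug_tonic_shift_pA=0.0, seed=7)
        trace, truth = synth.simulate_patch_trace(cfg)
        events = patch.detect_ipscs(trace, (0.0, 60.0))
        gt = truth.events_in(0.0, 60.0)
        tp = match_events([e.onset_s for e in events], gt)
        assert tp / len(gt) >= 0.9
        assert tp / len(events) >= 0.9
        taus = np.array([e.tau_decay_ms for e in events])
        taus = taus[np.isfinite(taus)]
        assert abs(taus.mean() - 10.0) / 10.0 < 0.1

    def test_zero_rate_trace_yields_no_events(self):
        cfg = synth.PatchSimConfig(ipsc_rate_hz=0.0, seed=8)
        trace, _ = synth.simulate_patch_trace(cfg)
        assert patch.detect_ipscs(trace, (0.0, 30.0)) == []

    def test_blocked_window_false_positive_rate_below_bound(self):
        total = 0.0
        for seed in (9, 10, 11):
            trace, _ = synth.simulate_patch_trace(synth.PatchSimConfig(seed=seed))
            total += len(patch.detect_ipscs(trace, (310.0, 340.0)))
        assert total / 90.0 < 0.05

    def test_sds_frequency_deficit_direction_recovered(self):
        # cohorts differing only in event rate: estimated frequency orders
        # the same way as the injected deficit
        freqs = {}
        for label, rate in (("naive", 3.0), ("sds", 1.0)):
            vals = []
            for seed in range(3):
                cfg = synth.PatchSimConfig(ipsc_rate_hz=rate, duration_s=120,
                                           drug_time_s=60, bicuculline_time_s=100,
                                           seed=100 + seed)
                trace, _ = synth.simulate_patch_trace(cfg)
                ev = patch.detect_ipscs(trace, (10.0, 40.0))
                vals.append(patch.summarize_ipscs(ev, (10.0, 40.0)).frequency_hz)
            freqs[label] = np.mean(vals)
        assert freqs["sds"] < freqs["naive"]


class TestSummaries:
    def test_frequency_is_count_over_window(self, default_patch):
        trace, _ = default_patch
        events = patch.detect_ipscs(trace, (0.0, 30.0))
        s = patch.summarize_ipscs(events, (0.0, 30.0))
        assert s.frequency_hz == pytest.approx(len(events) / 30.0)

    def test_empty_window_gives_nan_means_zero_frequency(self):
        s = patch.summarize_ipscs([], (0.0, 30.0))
        assert s.frequency_hz == 0.0
        assert np.isnan(s.mean_amplitude_pA)
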