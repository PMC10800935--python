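"""Amplitude/EMG exclusion rules, the inclusion gate, and interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdsephys import preprocess, synth
from sdsephys.errors import UnitError, ValidationError
from sdsephys.preprocess import BinMask
from sdsephys.trace_io import TraceRecording


def _rec(signal, fs=400.0, emg=None, unit="mV"):
    channels = {"lfp": np.asarray(signal, dtype=float)}
    units = {"lfp": unit}
    roles = {"lfp": "LFP"}
    if emg is not None:
        channels["emg"] = np.asarray(emg, dtype=float)
        units["emg"] = "mV"
        roles["emg"] = "EMG"
    return TraceRecording(channels=channels, fs_hz=fs, units=units, roles=roles)


def _mask(excluded, reason="amplitude"):
    excluded = np.asarray(excluded, dtype=bool)
    return BinMask(excluded=excluded,
                   reason=np.array([reason if e else "" for e in excluded], object))


class TestAmplitudeMask:
    def test_single_spike_excludes_only_its_bin(self):
        x = np.zeros(60 * 400)
        x[int(10.4 * 400)] = 3.0
        mask = preprocess.amplitude_mask(_rec(x), "lfp")
        assert mask.excluded_bins.tolist() == [10]
        assert mask.reason[10] == "amplitude"

    def test_signal_below_threshold_keeps_all_bins(self):
        mask = preprocess.amplitude_mask(_rec(np.full(30 * 400, 1.9)), "lfp")
        assert mask.excluded_fraction == 0.0

    def test_exactly_at_threshold_is_kept(self):
        # the rule is strict: "exceeded 2 mV"
        mask = preprocess.amplitude_mask(_rec(np.full(10 * 400, 2.0)), "lfp")
        assert mask.excluded_fraction == 0.0

    def test_injected_artifacts_recovered_exactly(self, short_session):
        rec, truth = short_session
        mask = preprocess.amplitude_mask(rec, "eeg")
        assert mask.excluded_bins.tolist() == truth.artifact_lfp_bins.tolist()

    def test_wrong_units_rejected(self):
        with pytest.raises(UnitError):
            preprocess.amplitude_mask(_rec(np.zeros(400), unit="uV"), "lfp")


class TestEmgMask:
    def test_injected_bursts_all_flagged(self, short_session):
        rec, truth = short_session
        _, mask = preprocess.emg_mask(rec)
        assert set(truth.artifact_emg_bins) <= set(mask.excluded_bins)

    def test_zero_emg_flags_nothing(self):
        rec = _rec(np.zeros(30 * 400), emg=np.zeros(30 * 400))
        feat, mask = preprocess.emg_mask(rec)
        assert mask.excluded_fraction == 0.0
        assert feat.threshold == 0.0

    def test_stationary_gaussian_emg_flags_upper_tail(self):
        # mean+1SD on a near-normal rms distribution excludes ~16% of bins
        rng = np.random.default_rng(0)
        n = 600
        rec = _rec(np.zeros(n * 400), emg=rng.standard_normal(n * 400) * 0.02)
        _, mask = preprocess.emg_mask(rec)
        assert abs(mask.excluded_fraction - 0.16) < 0.05

    def test_missing_emg_channel_is_precondition_error(self):
        with pytest.raises(ValidationError, match="EMG"):
            preprocess.emg_mask(_rec(np.zeros(400)))


class TestCombineAndGate:
    def test_union_merges_reasons(self):
        a = _mask([1, 0, 1, 0], "amplitude")
        b = _mask([1, 1, 0, 0], "emg")
        m = preprocess.combine_masks(a, b)
        assert m.excluded.tolist() == [True, True, True, False]
        assert m.reason[0] == "both"
        assert m.reason[1] == "emg"
        assert m.reason[2] == "amplitude"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            preprocess.combine_masks(_mask([1, 0]), _mask([1, 0, 0]))

    @pytest.mark.parametrize("n_excluded,expected", [(9, True), (10, False), (11, False)])
    def test_inclusion_rule_is_strictly_less_than_ten_percent(self, n_excluded, expected):
        excl = np.zeros(100, dtype=bool)
        excl[:n_excluded] = True
        assert preprocess.check_inclusion(_mask(excl)) is expected

    @given(st.lists(st.booleans(), min_size=5, max_size=40), st.integers(0, 2**16))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_union_fraction_at_least_each_input(self, bools, seed):
        rng = np.random.default_rng(seed)
        a = _mask(np.array(bools))
        b = _mask(rng.uniform(size=len(bools)) < 0.3, "emg")
        m = preprocess.combine_masks(a, b)
        assert m.excluded_fraction >= max(a.excluded_fraction, b.excluded_fraction)


class TestInterpolation:
    def test_interior_gap_is_midpoint(self):
        out = preprocess.interpolate_excluded([1.0, 99.0, 3.0], _mask([0, 1, 0]))
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0])

    def test_leading_gap_takes_nearest_included_value(self):
        out = preprocess.interpolate_excluded([99.0, 2.0, 2.0], _mask([1, 0, 0]))
        np.testing.assert_allclose(out, [2.0, 2.0, 2.0])

    def test_random_mask_on_linear_ramp_restores_ramp(self):
        rng = np.random.default_rng(1)
        ramp = np.arange(50.0)
        excl = rng.uniform(size=50) < 0.3
        excl[[0, -1]] = False  # keep endpoints so the ramp is recoverable
        out = preprocess.interpolate_excluded(ramp, _mask(excl))
        np.testing.assert_allclose(out, ramp, atol=1e-12)

    def test_included_bins_never_altered(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=40)
        excl = rng.uniform(size=40) < 0.25
        out = preprocess.interpolate_excluded(series, _mask(excl))
        np.testing.assert_array_equal(out[~excl], series[~excl])

    def test_interior_values_bounded_by_neighbors(self):
        series = np.array([1.0, 50.0, -50.0, 4.0])
        out = preprocess.interpolate_excluded(series, _mask([0, 1, 1, 0]))
        assert np.all(out >= 1.0) and np.all(out <= 4.0)

    def test_all_excluded_is_error(self):
        with pytest.raises(ValidationError):
            preprocess.interpolate_excluded([1.0, 2.0], _mask([1, 1]))


def test_masks_are_idempotent(short_session):
    rec, _ = short_session
    a1 = preprocess.amplitude_mask(rec, "eeg")
    a2 = preprocess.amplitude_mask(rec, "eeg")
    np.testing.assert_array_equal(a1.excluded, a2.excluded)
    _, e1 = preprocess.emg_mask(rec)
    _, e2 = preprocess.emg_mask(rec)
    np.testing.assert_array_equal(e1.excluded, e2.excluded)
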