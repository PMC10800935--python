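"""Per-bin spectra, normalization invariances, and pre/post summaries."""

import numpy as np
import pytest

from sdsephys import preprocess, spectral, synth
from sdsephys.errors import ValidationError
from sdsephys.preprocess import BinMask
from sdsephys.trace_io import TraceRecording


def _rec(signal, fs=2000.0, role="LFP"):
    name = role.lower()
    return TraceRecording(channels={name: np.asarray(signal, float)}, fs_hz=fs,
                          units={name: "mV"}, roles={name: role})


def _tone(freq=8.0, amp=0.1, dur=10, fs=2000.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _mask(excluded):
    excluded = np.asarray(excluded, dtype=bool)
    return BinMask(excluded=excluded,
                   reason=np.array(["amplitude" if e else "" for e in excluded], object))


class TestPerBinSpectrum:
    def test_tone_peak_at_its_frequency_with_half_amp_squared_power(self):
        spec = spectral.per_bin_spectrum(_rec(_tone()), "lfp")
        assert spec.freqs_hz[np.argmax(spec.power[0])] == 8.0
        np.testing.assert_allclose(
            spec.power[:, spec.freqs_hz == 8.0].sum(axis=1), 0.1**2 / 2, rtol=1e-6
        )

    def test_power_scales_with_amplitude_squared(self):
        s1 = spectral.per_bin_spectrum(_rec(_tone(amp=0.1)), "lfp")
        s10 = spectral.per_bin_spectrum(_rec(_tone(amp=1.0)), "lfp")
        np.testing.assert_allclose(s10.power, 100 * s1.power, rtol=1e-9, atol=1e-18)

    def test_parseval_with_rectangular_window(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5 * 2000) * 0.2
        spec = spectral.per_bin_spectrum(_rec(x), "lfp", window="boxcar")
        for b in range(5):
            seg = x[b * 2000 : (b + 1) * 2000]
            np.testing.assert_allclose(spec.power[b].sum(), np.mean(seg**2), rtol=1e-9)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200 * 2000) * 0.1
        spec = spectral.per_bin_spectrum(_rec(x), "lfp", window="boxcar")
        mean_spec = spec.power.mean(axis=0)[1:-1]  # drop DC and Nyquist
        # averaged over 200 bins, each 1-Hz line should sit near the mean level
        ratio = mean_spec / mean_spec.mean()
        assert np.all(np.abs(ratio - 1) < 0.35)

    def test_emg_channel_rejected(self):
        rec = TraceRecording(channels={"emg": np.zeros(4000)}, fs_hz=2000.0,
                             units={"emg": "mV"}, roles={"emg": "EMG"})
        with pytest.raises(ValidationError):
            spectral.per_bin_spectrum(rec, "emg")


class TestNormalizedBandPower:
    def test_tone_theta_ratio_near_one_beta_near_zero(self):
        spec = spectral.per_bin_spectrum(_rec(_tone()), "lfp")
        series = spectral.normalized_band_power(spec)
        assert np.all(series.bands["theta"] >= 0.99)
        assert np.all(series.bands["beta"] <= 0.01)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10 * 2000) * 0.05 + _tone()
        s1 = spectral.normalized_band_power(spectral.per_bin_spectrum(_rec(x), "lfp"))
        s2 = spectral.normalized_band_power(
            spectral.per_bin_spectrum(_rec(x * 37.5), "lfp")
        )
        for band in s1.bands:
            np.testing.assert_allclose(
                s1.bands[band], s2.bands[band], rtol=1e-10
            )

    def test_zero_power_in_included_bin_is_error(self):
        spec = spectral.per_bin_spectrum(_rec(np.zeros(5 * 2000)), "lfp")
        with pytest.raises(ValidationError, match="zero total power"):
            spectral.normalized_band_power(spec)

    def test_band_outside_normalization_range_rejected(self):
        spec = spectral.per_bin_spectrum(_rec(_tone()), "lfp")
        wide = spectral.BandDefinition("hf", 90.0, 120.0)
        with pytest.raises(ValidationError):
            spectral.normalized_band_power(spec, bands=(wide,),
                                           normalization_range_hz=(1, 100))

    def test_excluded_bins_never_influence_summaries(self):
        # corrupt the signal inside excluded bins only; series must not change
        rng = np.random.default_rng(3)
        base = rng.standard_normal(20 * 2000) * 0.05 + _tone(dur=20)
        corrupt = base.copy()
        excl = np.zeros(20, dtype=bool)
        excl[[5, 11, 12]] = True
        for b in np.flatnonzero(excl):
            corrupt[b * 2000 : (b + 1) * 2000] = rng.standard_normal(2000) * 5
        mask = _mask(excl)
        s_base = spectral.normalized_band_power(
            spectral.per_bin_spectrum(_rec(base), "lfp"), mask=mask
        )
        s_corr = spectral.normalized_band_power(
            spectral.per_bin_spectrum(_rec(corrupt), "lfp"), mask=mask
        )
        for band in s_base.bands:
            np.testing.assert_allclose(s_base.bands[band], s_corr.bands[band])


class TestPrePostSummary:
    def test_constant_series_gives_ratio_one(self):
        t = np.arange(3600.0)
        pp = spectral.pre_post_summary(np.full(3600, 0.4), t, 1800.0)
        assert pp.pre_mean == pp.post_mean == pytest.approx(0.4)
        assert pp.post_over_pre == pytest.approx(1.0)

    def test_step_doubling_at_drug_time_gives_ratio_two(self):
        t = np.arange(3600.0)
        series = np.where(t >= 1800, 2.0, 1.0)
        pp = spectral.pre_post_summary(series, t, 1800.0)
        assert pp.post_over_pre == pytest.approx(2.0)

    def test_windows_beyond_recording_rejected(self):
        with pytest.raises(ValidationError):
            spectral.pre_post_summary(np.ones(100), np.arange(100.0), 50.0)

    def test_injected_sqrt2_gain_recovered_as_power_ratio_two(self):
        # amplitude gain sqrt(2) at the drug mark => raw band power x2
        ratios = []
        for seed in range(5):
            cfg = synth.LfpSimConfig(
                duration_s=3600, fs_hz=400, channel_role="EEG",
                background_sd_mV=0.02,
                band_components=(synth.BandComponent(8.0, 4.0, 0.1),),
                drug_band_gain=(np.sqrt(2.0),), seed=seed,
            )
            rec, _ = synth.simulate_lfp_session(cfg)
            spec = spectral.per_bin_spectrum(rec, "eeg")
            series = spectral.raw_band_power(spec, spectral.THETA)
            ratios.append(
                spectral.pre_post_summary(series, spec.bin_times_s, 1800.0).post_over_pre
            )
        assert abs(np.mean(ratios) - 2.0) < 0.2


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        res = spectral.baseline_group_compare(a, a.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_five_sd_shift_detected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(20):
            a = rng.normal(0, 1, 10)
            b = rng.normal(5, 1, 10)
            if spectral.baseline_group_compare(a, b).p_raw < 0.05:
                rejections += 1
        assert rejections == 20

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        r1 = spectral.baseline_group_compare(a, b)
        r2 = spectral.baseline_group_compare(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            spectral.baseline_group_compare([1.0], [2.0, 3.0])


def test_drug_vehicle_ratio():
    assert spectral.drug_vehicle_ratio(2.0, 1.0) == pytest.approx(2.0)
    with pytest.raises(ValidationError):
        spectral.drug_vehicle_ratio(2.0, 0.0)
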