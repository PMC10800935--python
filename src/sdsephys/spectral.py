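"""Per-bin spectral decomposition and drug-effect summaries.

Each 1-s bin of an LFP/EEG channel gets its own power spectrum (1-Hz
resolution).  Band powers (theta = [6, 12) Hz, beta = [15, 30) Hz) are
normalized per bin by the total power over a configurable range (default
1–100 Hz), so the series is a unitless ratio invariant to overall signal
scaling.  Drug effects are summarized as the mean normalized power over the
15 min before administration versus the window 15–30 min after.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import stats as _stats
from .errors import ValidationError
from .preprocess import BinMask, interpolate_excluded
from .trace_io import TraceRecording


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, half-open [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"[{self.low_hz}, {self.high_hz})"
            )


THETA = BandDefinition("theta", 6.0, 12.0)
BETA = BandDefinition("beta", 15.0, 30.0)
DEFAULT_BANDS = (THETA, BETA)
DEFAULT_NORM_RANGE = (1.0, 100.0)

PRE_WINDOW_MIN = 15.0          # [drug - 15 min, drug)
POST_WINDOW_MIN = (15.0, 30.0)  # [drug + 15 min, drug + 30 min)


@dataclass
class Spectrogram:
    """Per-1-s-bin power spectra at 1-Hz resolution."""

    freqs_hz: np.ndarray          # (n_freq,)
    power: np.ndarray             # (n_bins, n_freq)
    bin_times_s: np.ndarray       # left edge of each bin

    @property
    def n_bins(self) -> int:
        return self.power.shape[0]


@dataclass
class BandPowerSeries:
    """Per-bin normalized band power, with the mask that was applied."""

    bands: dict[str, np.ndarray]
    bin_times_s: np.ndarray
    normalization_range_hz: tuple[float, float]
    mask: BinMask | None = None


@dataclass
class PrePostSummary:
    """Mean normalized power before vs after drug administration."""

    pre_mean: float
    post_mean: float
    windows_s: dict = field(default_factory=dict)

    @property
    def post_over_pre(self) -> float:
        if self.pre_mean <= 0:
            raise ValidationError("pre-administration mean power is not positive")
        return self.post_mean / self.pre_mean


def per_bin_spectrum(
    rec: TraceRecording,
    channel: str,
    window: str = "hann",
) -> Spectrogram:
    """One power spectrum per 1-s bin of the given LFP/EEG channel.

    Power uses scipy's 'spectrum' scaling: a pure tone of amplitude A
    contributes A^2/2 at its frequency bin.  A Hann taper (with amplitude
    correction) is applied by default; pass ``window='boxcar'`` for a plain
    rectangular transform (which makes the per-bin power sum equal the
    time-domain mean square, Parseval).
    """
    if channel not in rec.channels:
        raise ValidationError(f"no channel {channel!r}")
    if rec.roles[channel] not in ("LFP", "EEG"):
        raise ValidationError(
            f"spectral analysis applies to LFP/EEG, not {rec.roles[channel]}"
        )
    fs = int(round(rec.fs_hz))
    nb = int(rec.n_samples // fs)
    if nb < 1:
        raise ValidationError("recording shorter than one 1-s bin")
    x = rec.channels[channel][: nb * fs].reshape(nb, fs)
    freqs, power = sps.periodogram(
        x, fs=fs, window=window, detrend=False, scaling="spectrum", axis=1
    )
    return Spectrogram(
        freqs_hz=freqs, power=power, bin_times_s=np.arange(nb, dtype=float)
    )


def band_slice(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    """Boolean selector for the half-open band [low, high)."""
    return (freqs >= low) & (freqs < high)


def raw_band_power(spec: Spectrogram, band: BandDefinition) -> np.ndarray:
    """Per-bin absolute power in a band (mV^2), without normalization.

    Useful for recovering injected amplitude effects: a gain g on a band
    component multiplies its raw band power by g^2, whereas the normalized
    ratio is compressed by the change in total power.
    """
    if band.high_hz > spec.freqs_hz[-1]:
        raise ValidationError(f"band {band.name!r} beyond Nyquist")
    return spec.power[:, band_slice(spec.freqs_hz, band.low_hz, band.high_hz)].sum(axis=1)


def normalized_band_power(
    spec: Spectrogram,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    normalization_range_hz: tuple[float, float] = DEFAULT_NORM_RANGE,
    mask: BinMask | None = None,
) -> BandPowerSeries:
    """Per-bin band power divided by per-bin total power.

    Excluded bins (per ``mask``) are filled by linear interpolation of the
    normalized series, so their raw spectra never reach the summaries.
    """
    lo, hi = normalization_range_hz
    nyq = spec.freqs_hz[-1]
    for b in bands:
        if not (lo <= b.low_hz and b.high_hz <= hi):
            raise ValidationError(
                f"band {b.name!r} outside normalization range [{lo}, {hi}]"
            )
        if b.high_hz > nyq:
            raise ValidationError(f"band {b.name!r} beyond Nyquist {nyq} Hz")
    total = spec.power[:, band_slice(spec.freqs_hz, lo, hi)].sum(axis=1)
    included = (
        ~mask.excluded if mask is not None else np.ones(spec.n_bins, dtype=bool)
    )
    if mask is not None and mask.n_bins != spec.n_bins:
        raise ValidationError("mask length does not match the spectrogram")
    if np.any(total[included] <= 0):
        raise ValidationError("zero total power in an included bin")

    out = {}
    for b in bands:
        sel = band_slice(spec.freqs_hz, b.low_hz, b.high_hz)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = spec.power[:, sel].sum(axis=1) / total
        if mask is not None:
            ratio = interpolate_excluded(np.where(included, ratio, np.nan), mask)
        out[b.name] = ratio
    return BandPowerSeries(
        bands=out,
        bin_times_s=spec.bin_times_s,
        normalization_range_hz=normalization_range_hz,
        mask=mask,
    )


def pre_post_summary(
    series: np.ndarray,
    bin_times_s: np.ndarray,
    drug_time_s: float,
) -> PrePostSummary:
    """Mean of a per-bin series over the pre and post drug windows.

    Pre = [drug - 15 min, drug); post = [drug + 15 min, drug + 30 min).
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(bin_times_s, dtype=float)
    pre_lo = drug_time_s - PRE_WINDOW_MIN * 60
    post_lo = drug_time_s + POST_WINDOW_MIN[0] * 60
    post_hi = drug_time_s + POST_WINDOW_MIN[1] * 60
    if pre_lo < t[0] or post_hi > t[-1] + 1:
        raise ValidationError(
            "pre/post windows extend beyond the recording "
            f"([{pre_lo}, {post_hi}] s vs [{t[0]}, {t[-1] + 1}] s)"
        )
    pre_sel = (t >= pre_lo) & (t < drug_time_s)
    post_sel = (t >= post_lo) & (t < post_hi)
    return PrePostSummary(
        pre_mean=float(series[pre_sel].mean()),
        post_mean=float(series[post_sel].mean()),
        windows_s={"pre": (pre_lo, drug_time_s), "post": (post_lo, post_hi)},
    )


def drug_vehicle_ratio(post_over_pre_drug: float, post_over_pre_vehicle: float) -> float:
    """Drug-normalized effect: (post/pre under drug) / (post/pre under vehicle)."""
    if post_over_pre_vehicle <= 0:
        raise ValidationError("vehicle post/pre ratio must be positive")
    return post_over_pre_drug / post_over_pre_vehicle


def baseline_group_compare(
    pre_means_a: np.ndarray, pre_means_b: np.ndarray
) -> "_stats.TestResult":
    """Unpaired comparison of per-subject pre-administration means.

    Each entry is one subject's pre-window mean (averaged across arms when a
    subject was recorded under several drugs).
    """
    a = np.asarray(pre_means_a, dtype=float)
    b = np.asarray(pre_means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two subjects per group")
    return _stats.unpaired_t(a, b)
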