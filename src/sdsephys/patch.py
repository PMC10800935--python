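"""Tonic current estimation and sIPSC characterization from voltage clamp.

Tonic GABAergic current is measured with the holding-current histogram
procedure: the mean current of 10-ms epochs sampled every 100 ms is
histogrammed over a 30-s window before and after bicuculline, each
histogram is fit with a Gaussian, and the difference of the fitted means is
the tonic current (positive = outward shift upon block = magnitude of the
tonic inhibitory current).  Spontaneous IPSCs are detected as inward
deflections exceeding 3x the robust noise SD, and each event's decay is fit
with a single exponential to give tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import FitError, ValidationError
from .trace_io import PatchTrace

EPOCH_WIDTH_S = 0.010
EPOCH_SPACING_S = 0.100
TONIC_WINDOW_S = 30.0
QC_MAX_CHANGE_FRAC = 0.30
DETECT_THRESHOLD_SD = 3.0
MIN_EVENT_INTERVAL_S = 0.005
FIT_GOODNESS_WARN = 0.8


class GaussianFitWarning(UserWarning):
    """Raised when the holding-current histogram is poorly fit by a Gaussian."""


@dataclass
class EpochCurrentSample:
    """Mean current per 10-ms epoch, one epoch every 100 ms from t=0."""

    epoch_means_pA: np.ndarray
    epoch_times_s: np.ndarray  # epoch centers

    def in_window(self, start_s: float, stop_s: float) -> np.ndarray:
        sel = (self.epoch_times_s >= start_s) & (self.epoch_times_s < stop_s)
        return self.epoch_means_pA[sel]


@dataclass
class TonicEstimate:
    """Gaussian-fit holding currents for a condition window vs the blocked window."""

    window_a_s: tuple[float, float]
    window_b_s: tuple[float, float]
    fitted_mean_a_pA: float
    fitted_mean_b_pA: float
    fitted_sd_pA: float
    fit_goodness: float

    @property
    def tonic_pA(self) -> float:
        """Positive = outward shift upon bicuculline = tonic inhibition magnitude."""
        return self.fitted_mean_b_pA - self.fitted_mean_a_pA


@dataclass
class IPSCEvent:
    onset_s: float
    peak_s: float
    amplitude_pA: float        # magnitude of the inward deflection
    tau_decay_ms: float        # NaN if the exponential fit failed
    fit_r2: float


@dataclass
class IPSCSummary:
    mean_amplitude_pA: float
    frequency_hz: float
    mean_tau_ms: float
    n_events: int


def qc_cell(trace: PatchTrace, max_change_frac: float = QC_MAX_CHANGE_FRAC) -> bool:
    """Keep the cell unless series resistance or capacitance drifted >30%."""
    try:
        rs = trace.qc["series_resistance_change_frac"]
        cm = trace.qc["capacitance_change_frac"]
    except KeyError as exc:
        raise ValidationError(f"missing qc metadata: {exc}") from exc
    return not (rs > max_change_frac or cm > max_change_frac)


def sample_epoch_means(trace: PatchTrace) -> EpochCurrentSample:
    """Mean current during 10-ms epochs collected every 100 ms from t=0."""
    fs = trace.fs_hz
    if fs < 1000:
        raise ValidationError("need fs >= 1 kHz for 10-ms epochs")
    n_per = int(round(EPOCH_WIDTH_S * fs))
    stride = int(round(EPOCH_SPACING_S * fs))
    x = trace.current_pA
    if len(x) < n_per:
        raise ValidationError("trace shorter than one 10-ms epoch")
    starts = np.arange(0, len(x) - n_per + 1, stride)
    means = np.array([x[s : s + n_per].mean() for s in starts])
    times = starts / fs + EPOCH_WIDTH_S / 2
    return EpochCurrentSample(epoch_means_pA=means, epoch_times_s=times)


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_holding(values: np.ndarray) -> tuple[float, float, float]:
    """Fit a Gaussian to the histogram of epoch means.

    Returns (mu_pA, sigma_pA, goodness) where goodness is the R^2 of the
    histogram fit; a degenerate sample (all identical) returns
    (value, 0, 1) without fitting.  Poor fits (goodness < 0.8, e.g. a
    bimodal holding current) emit a :class:`GaussianFitWarning`.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 50:
        raise ValidationError(f"need >= 50 epochs for a stable fit, got {len(values)}")
    if np.ptp(values) == 0:
        return float(values[0]), 0.0, 1.0
    counts, edges = np.histogram(values, bins="fd")
    if len(counts) < 4:
        counts, edges = np.histogram(values, bins=8)
    centers = (edges[:-1] + edges[1:]) / 2
    p0 = (counts.max(), values.mean(), max(values.std(), 1e-9))
    try:
        popt, _ = optimize.curve_fit(_gaussian, centers, counts, p0=p0, maxfev=5000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    resid = counts - _gaussian(centers, *popt)
    ss_tot = ((counts - counts.mean()) ** 2).sum()
    goodness = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    if goodness < FIT_GOODNESS_WARN:
        warnings.warn(
            f"holding-current histogram poorly fit by a Gaussian (R^2 = "
            f"{goodness:.2f}); distribution may be multimodal",
            GaussianFitWarning,
            stacklevel=2,
        )
    return float(popt[1]), float(abs(popt[2])), float(goodness)


def _check_window(name: str, win: tuple[float, float], trace: PatchTrace) -> None:
    lo, hi = win
    if not (0 <= lo < hi <= trace.duration_s + 1e-9):
        raise ValidationError(f"{name} window [{lo}, {hi}] s outside the trace")


def estimate_tonic(
    trace: PatchTrace,
    condition_window: tuple[float, float] | None = None,
    bicuculline_window: tuple[float, float] | None = None,
) -> TonicEstimate:
    """Tonic current from 30-s condition vs bicuculline windows.

    Defaults: condition window = the 30 s before the ``bicuculline`` marker,
    blocked window = the 30 s after it.  The condition window must not
    overlap the bicuculline onset.
    """
    bic = trace.markers.get("bicuculline")
    if condition_window is None or bicuculline_window is None:
        if bic is None:
            raise ValidationError(
                "no bicuculline marker; pass explicit windows instead"
            )
        condition_window = condition_window or (bic - TONIC_WINDOW_S, bic)
        bicuculline_window = bicuculline_window or (bic, bic + TONIC_WINDOW_S)
    _check_window("condition", condition_window, trace)
    _check_window("bicuculline", bicuculline_window, trace)
    if bic is not None and condition_window[1] > bic + 1e-9:
        raise ValidationError(
            f"condition window {condition_window} overlaps bicuculline onset at {bic} s"
        )
    if condition_window[1] > bicuculline_window[0] + 1e-9:
        raise ValidationError("condition and bicuculline windows overlap")

    epochs = sample_epoch_means(trace)
    vals_a = epochs.in_window(*condition_window)
    vals_b = epochs.in_window(*bicuculline_window)
    mu_a, _, good_a = fit_gaussian_holding(vals_a)
    mu_b, sd_b, good_b = fit_gaussian_holding(vals_b)
    return TonicEstimate(
        window_a_s=tuple(condition_window),
        window_b_s=tuple(bicuculline_window),
        fitted_mean_a_pA=mu_a,
        fitted_mean_b_pA=mu_b,
        fitted_sd_pA=sd_b,
        fit_goodness=min(good_a, good_b),
    )


def pre_post_tonic(trace: PatchTrace) -> tuple[TonicEstimate, TonicEstimate]:
    """Pre-drug and post-drug tonic estimates against the same blocked window.

    Pretonic pairs the 30 s immediately before drug onset with the
    bicuculline window; posttonic pairs the last 30 s of the drug period
    (immediately before bicuculline) with the same blocked window.
    """
    drug = trace.markers.get("drug_admin")
    bic = trace.markers.get("bicuculline")
    if drug is None or bic is None:
        raise ValidationError("trace needs drug_admin and bicuculline markers")
    pre = estimate_tonic(trace, (drug - TONIC_WINDOW_S, drug))
    post = estimate_tonic(trace, (bic - TONIC_WINDOW_S, bic))
    return pre, post


def drug_tonic_potentiation(pre: TonicEstimate, post: TonicEstimate) -> float:
    """Drug-induced tonic potentiation in pA: posttonic - pretonic."""
    return post.tonic_pA - pre.tonic_pA


# ---------------------------------------------------------------------------
# sIPSC detection and kinetics
# ---------------------------------------------------------------------------

def _baseline(x: np.ndarray, fs: float) -> np.ndarray:
    """Slow baseline via chunked medians (robust to sparse inward events)."""
    chunk = max(int(round(0.1 * fs)), 1)
    nb = max(len(x) // chunk, 1)
    med = np.array([np.median(x[i * chunk : (i + 1) * chunk]) for i in range(nb)])
    centers = (np.arange(nb) + 0.5) * chunk
    return np.interp(np.arange(len(x)), centers, med)


def _cb_template(fs: float, rise_ms: float, tau_ms: float,
                 pad_ms: float = 5.0) -> tuple[np.ndarray, int]:
    """Peak-normalized difference-of-exponentials template with baseline pad.

    The flat pre-onset pad makes the criterion sensitive to the sharp rise:
    a window sliding along a smooth decay tail fits with near-zero scale.
    Returns (template, pad_samples); the event onset sits ``pad_samples``
    into the window.
    """
    tau_r = rise_ms / 1000
    tau_d = tau_ms / 1000
    pad = int(pad_ms / 1000 * fs)
    tk = np.arange(int((3 * tau_r + 5 * tau_d) * fs)) / fs
    shape = np.exp(-tk / tau_d) - np.exp(-tk / tau_r)
    tpl = np.concatenate([np.zeros(pad), shape / shape.max()])
    return tpl, pad


def detect_ipscs(
    trace: PatchTrace,
    window: tuple[float, float],
    threshold_sd: float = DETECT_THRESHOLD_SD,
    dc_threshold: float = 4.0,
    template_rise_ms: float = 1.0,
    template_tau_ms: float = 10.0,
    fit_decay: bool = True,
) -> list[IPSCEvent]:
    """Detect inward synaptic events in a window and fit their decays.

    Detection is a sliding-template criterion (Clements-Bekkers): at each
    offset the peak-normalized event template is least-squares fit (scale +
    offset) to the baseline-subtracted inward deflection, and the t-like
    detection criterion ``scale / SE(scale)`` must exceed ``dc_threshold``.
    Accepted events must additionally exceed ``threshold_sd`` times the
    MAD-based robust noise SD in fitted amplitude, and be separated by at
    least 5 ms.  Each event's decay from its measured peak is fit with
    ``a * exp(-t/tau)``; events whose fit fails keep tau = NaN.
    """
    lo, hi = window
    _check_window("detection", window, trace)
    fs = trace.fs_hz
    i0, i1 = int(round(lo * fs)), int(round(hi * fs))
    x = trace.current_pA[i0:i1].astype(float)
    if fs > 2500:
        sos = signal.butter(4, 1000.0, btype="lowpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    d = _baseline(x, fs) - x  # positive = inward deflection
    mad = np.median(np.abs(d - np.median(d)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        return []

    tpl, pad = _cb_template(fs, template_rise_ms, template_tau_ms)
    n = len(tpl)
    if n >= len(d):
        raise ValidationError("detection window shorter than the event template")
    st, stt = tpl.sum(), (tpl**2).sum()
    sttc = stt - st**2 / n
    ones = np.ones(n)
    sy = signal.fftconvolve(d, ones, mode="valid")
    syy = signal.fftconvolve(d * d, ones, mode="valid")
    sty = signal.fftconvolve(d, tpl[::-1], mode="valid")
    scale = (sty - st * sy / n) / sttc
    rss = np.maximum(syy - sy**2 / n - scale**2 * sttc, 1e-12)
    dc = scale * np.sqrt(sttc) / np.sqrt(rss / (n - 2))

    min_dist = max(int(MIN_EVENT_INTERVAL_S * fs), 1)
    starts, _ = signal.find_peaks(dc, height=dc_threshold, distance=min_dist)
    # template peak lag relative to the event onset inside the window
    lag = int(np.argmax(tpl)) - pad
    events: list[IPSCEvent] = []
    base_n = max(int(0.003 * fs), 1)
    for k, s in enumerate(starts):
        onset_i = s + pad
        p = onset_i + np.argmax(d[onset_i : onset_i + max(3 * lag, min_dist)])
        # two acceptance rules: the template-fit scale must clear the noise
        # floor, and the peak must rise above the local pre-onset baseline
        # (a candidate riding a preceding event's decay has no rise)
        local_base = float(np.median(d[max(onset_i - base_n, 0) : max(onset_i, 1)]))
        amp = float(d[p]) - local_base
        if scale[s] <= threshold_sd * noise_sd or amp <= threshold_sd * noise_sd:
            continue
        tau_ms, r2 = np.nan, np.nan
        if fit_decay:
            nxt = starts[k + 1] + pad if k + 1 < len(starts) else len(d)
            tau_ms, r2 = _fit_decay(d, int(p), fs, int(min(nxt, len(d))))
        events.append(
            IPSCEvent(
                onset_s=float(lo + onset_i / fs),
                peak_s=float(lo + p / fs),
                amplitude_pA=amp,
                tau_decay_ms=tau_ms,
                fit_r2=r2,
            )
        )
    return events


def _fit_decay(d: np.ndarray, peak: int, fs: float, next_peak: int) -> tuple[float, float]:
    """Single-exponential fit to the decay phase; returns (tau_ms, r2)."""
    amp = d[peak]
    # initial tau from the 63%-decay crossing
    target = amp * np.exp(-1)
    j = peak
    limit = min(next_peak, len(d))
    while j < limit - 1 and d[j] > target:
        j += 1
    tau0 = max((j - peak) / fs, 2 / fs)
    end = min(peak + int(5 * tau0 * fs), limit)
    if end - peak < 4:
        return np.nan, np.nan
    tt = np.arange(end - peak) / fs
    yy = d[peak:end]
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            tt, yy, p0=(amp, min(max(tau0, 1e-4), 0.5)),
            bounds=([0, 1e-4], [10 * max(amp, 1e-9), 1.0]), maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return np.nan, np.nan
    resid = yy - popt[0] * np.exp(-tt / popt[1])
    ss_tot = ((yy - yy.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    return float(popt[1] * 1000), float(r2)


def summarize_ipscs(events: list[IPSCEvent], window: tuple[float, float]) -> IPSCSummary:
    """Mean amplitude, frequency (count / window length) and mean tau."""
    lo, hi = window
    if hi <= lo:
        raise ValidationError("window must have positive length")
    dur = hi - lo
    inside = [e for e in events if lo <= e.onset_s < hi]
    amps = np.array([e.amplitude_pA for e in inside])
    taus = np.array([e.tau_decay_ms for e in inside])
    taus = taus[np.isfinite(taus)]
    return IPSCSummary(
        mean_amplitude_pA=float(amps.mean()) if len(amps) else np.nan,
        frequency_hz=len(inside) / dur,
        mean_tau_ms=float(taus.mean()) if len(taus) else np.nan,
        n_events=len(inside),
    )
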