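"""Synthetic data generation for all three modalities, with ground truth.

The generator emulates the study design the pipeline targets: 60-min
home-cage LFP (2 kHz) or EEG (400 Hz) sessions with co-recorded EMG and a
drug administration at the 30-min mark; whole-cell voltage-clamp current
traces with Poisson sIPSC trains, a drug-induced tonic shift and full
GABAergic block by bicuculline at the end; and behavioral cohorts with a
depression-like subpopulation assessed by SIT/TST/OFT.  Every injected
feature (artifact bins, event times, effect magnitudes) is recorded in a
ground-truth object so downstream estimators can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trace_io import PatchTrace, TraceRecording

__all__ = [
    "BandComponent",
    "ArtifactEpoch",
    "LfpSimConfig",
    "LfpGroundTruth",
    "simulate_lfp_session",
    "PatchSimConfig",
    "PatchGroundTruth",
    "simulate_patch_trace",
    "BehaviorSimConfig",
    "simulate_behavior_cohort",
]


# ---------------------------------------------------------------------------
# LFP / EEG sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandComponent:
    """A narrowband oscillatory component.

    ``bandwidth_hz == 0`` gives a pure sinusoid of peak amplitude
    ``amplitude_mV``; otherwise band-limited Gaussian noise of RMS
    ``amplitude_mV`` confined to ``center_hz ± bandwidth_hz/2``.
    """

    center_hz: float
    bandwidth_hz: float = 0.0
    amplitude_mV: float = 0.1


@dataclass(frozen=True)
class ArtifactEpoch:
    """A movement-artifact epoch: LFP deflection plus EMG burst.

    ``lfp_amp_mV`` is the peak deflection added to the LFP/EEG channel
    (0 for an EMG-only artifact); ``emg_gain`` multiplies the EMG noise SD
    within the epoch (1 for an LFP-only artifact).
    """

    start_s: float
    dur_s: float
    lfp_amp_mV: float = 5.0
    emg_gain: float = 5.0


@dataclass
class LfpSimConfig:
    """Home-cage session design: 60 min, drug at 30 min, LFP 2 kHz.

    Use ``fs_hz=400`` with ``channel_role='EEG'`` for EEG sessions.
    """

    duration_s: float = 3600.0
    fs_hz: float = 2000.0
    channel_role: str = "LFP"
    background_exponent: float = 1.0
    background_sd_mV: float = 0.05
    band_components: tuple[BandComponent, ...] = (
        BandComponent(8.0, 4.0, 0.05),    # theta, 6-12 Hz
        BandComponent(22.0, 10.0, 0.03),  # beta, 15-30 Hz
    )
    drug_time_s: float = 1800.0
    drug_band_gain: tuple[float, ...] = ()
    artifact_epochs: tuple[ArtifactEpoch, ...] = ()
    emg_noise_sd_mV: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be > 0, got {self.fs_hz}")
        for comp in self.band_components:
            top = comp.center_hz + comp.bandwidth_hz / 2
            if self.fs_hz <= 2 * top:
                raise ValidationError(
                    f"fs_hz={self.fs_hz} too low for component up to {top} Hz"
                )
            if comp.amplitude_mV < 0:
                raise ValidationError("component amplitude must be >= 0")
        if not 0 <= self.drug_time_s <= self.duration_s:
            raise ValidationError("drug_time_s outside [0, duration_s]")
        if self.drug_band_gain and len(self.drug_band_gain) != len(self.band_components):
            raise ValidationError(
                "drug_band_gain must match band_components in length"
            )
        if self.emg_noise_sd_mV < 0 or self.background_sd_mV < 0:
            raise ValidationError("noise SDs must be >= 0")


@dataclass
class LfpGroundTruth:
    """Everything injected into a simulated session."""

    drug_time_s: float
    components: tuple[BandComponent, ...]
    band_gains: tuple[float, ...]
    artifact_lfp_bins: np.ndarray = field(default_factory=lambda: np.array([], int))
    artifact_emg_bins: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def artifact_bins(self) -> np.ndarray:
        return np.union1d(self.artifact_lfp_bins, self.artifact_emg_bins)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                sd: float) -> np.ndarray:
    """1/f^alpha noise by spectral shaping of white noise, scaled to SD."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2)
    x = np.fft.irfft(spec * shape, n)
    return x * (sd / np.std(x))


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float,
                hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise spectrally confined to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _epoch_bins(start_s: float, dur_s: float, n_bins: int) -> np.ndarray:
    """1-s bins overlapped by [start, start+dur), half-open convention."""
    first = int(np.floor(start_s))
    last = int(np.ceil(start_s + dur_s))
    return np.arange(max(first, 0), min(last, n_bins))


def simulate_lfp_session(config: LfpSimConfig) -> tuple[TraceRecording, LfpGroundTruth]:
    """Simulate one home-cage session: signal channel + EMG, plus truth.

    The signal channel is 1/f background plus the configured oscillatory
    components; each component's amplitude is multiplied by its drug gain
    from ``drug_time_s`` onward.  Artifact epochs add a square deflection to
    the signal channel and scale the EMG noise.  Identical configs (same
    seed) produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz
    post = t >= config.drug_time_s
    gains = config.drug_band_gain or tuple(1.0 for _ in config.band_components)

    sig = _pink_noise(rng, n, config.fs_hz, config.background_exponent,
                      config.background_sd_mV)
    for comp, gain in zip(config.band_components, gains):
        env = np.where(post, gain, 1.0)
        if comp.bandwidth_hz == 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + env * comp.amplitude_mV * np.sin(
                2 * np.pi * comp.center_hz * t + phase
            )
        else:
            lo = comp.center_hz - comp.bandwidth_hz / 2
            hi = comp.center_hz + comp.bandwidth_hz / 2
            sig = sig + env * comp.amplitude_mV * _band_noise(
                rng, n, config.fs_hz, lo, hi
            )

    emg = rng.standard_normal(n) * config.emg_noise_sd_mV

    n_bins = int(config.duration_s)
    lfp_bins, emg_bins = [], []
    for ep in config.artifact_epochs:
        i0 = int(round(ep.start_s * config.fs_hz))
        i1 = min(int(round((ep.start_s + ep.dur_s) * config.fs_hz)), n)
        if i1 <= i0:
            continue
        if ep.lfp_amp_mV > 0:
            sig[i0:i1] += ep.lfp_amp_mV
            lfp_bins.append(_epoch_bins(ep.start_s, ep.dur_s, n_bins))
        if ep.emg_gain != 1.0:
            emg[i0:i1] *= ep.emg_gain
            emg_bins.append(_epoch_bins(ep.start_s, ep.dur_s, n_bins))

    role = config.channel_role
    rec = TraceRecording(
        channels={role.lower(): sig, "emg": emg},
        fs_hz=config.fs_hz,
        units={role.lower(): "mV", "emg": "mV"},
        roles={role.lower(): role, "emg": "EMG"},
        markers={"drug_admin": config.drug_time_s},
    )
    truth = LfpGroundTruth(
        drug_time_s=config.drug_time_s,
        components=tuple(config.band_components),
        band_gains=tuple(gains),
        artifact_lfp_bins=(
            np.unique(np.concatenate(lfp_bins)) if lfp_bins else np.array([], int)
        ),
        artifact_emg_bins=(
            np.unique(np.concatenate(emg_bins)) if emg_bins else np.array([], int)
        ),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Patch-clamp traces
# ---------------------------------------------------------------------------

@dataclass
class PatchSimConfig:
    """Voltage-clamp trace design.

    Currents are in pA with inward negative.  ``baseline_tonic_pA`` and
    ``drug_tonic_shift_pA`` are signed currents added to the trace (negative
    = inward tonic inhibition); both, and all synaptic events, are removed
    after ``bicuculline_time_s``.
    """

    duration_s: float = 360.0
    fs_hz: float = 10_000.0
    baseline_pA: float = -100.0
    noise_sd_pA: float = 5.0
    ipsc_rate_hz: float = 2.0
    ipsc_amp_mean_pA: float = 50.0
    ipsc_amp_cv: float = 0.3
    ipsc_tau_ms: float = 10.0
    ipsc_rise_ms: float = 1.0
    baseline_tonic_pA: float = -10.0
    drug_time_s: float = 60.0
    drug_tonic_shift_pA: float = -15.0
    drug_amp_gain: float = 1.3
    drug_tau_gain: float = 1.3
    bicuculline_time_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValidationError("duration_s and fs_hz must be > 0")
        if self.noise_sd_pA < 0 or self.ipsc_rate_hz < 0:
            raise ValidationError("noise SD and event rate must be >= 0")
        if self.ipsc_tau_ms <= 0 or self.ipsc_rise_ms <= 0:
            raise ValidationError("kinetic time constants must be > 0")
        if not self.bicuculline_time_s > self.drug_time_s:
            raise ValidationError("bicuculline must come after the drug")
        if self.bicuculline_time_s > self.duration_s:
            raise ValidationError("bicuculline_time_s outside the trace")
        kernel_s = 10 * self.ipsc_tau_ms * max(self.drug_tau_gain, 1.0) / 1000
        if kernel_s >= self.duration_s:
            raise ValidationError("event kernel longer than the trace")


@dataclass
class PatchGroundTruth:
    """Injected events and tonic schedule of a simulated patch trace."""

    event_times_s: np.ndarray
    event_amps_pA: np.ndarray      # signed (negative = inward)
    event_taus_ms: np.ndarray
    baseline_tonic_pA: float
    drug_tonic_shift_pA: float
    drug_time_s: float
    bicuculline_time_s: float

    def events_in(self, start_s: float, stop_s: float) -> np.ndarray:
        sel = (self.event_times_s >= start_s) & (self.event_times_s < stop_s)
        return self.event_times_s[sel]


def _ipsc_kernel(fs: float, amp_pA: float, tau_ms: float, rise_ms: float) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized, inward (negative)."""
    tau_d = tau_ms / 1000
    tau_r = rise_ms / 1000
    dur = 8 * tau_d
    tk = np.arange(int(dur * fs)) / fs
    shape = np.exp(-tk / tau_d) - np.exp(-tk / tau_r)
    peak = shape.max()
    return -amp_pA * shape / peak


def simulate_patch_trace(config: PatchSimConfig) -> tuple[PatchTrace, PatchGroundTruth]:
    """Simulate a voltage-clamp recording with known events and tonic steps.

    Trace = holding baseline + Gaussian noise + Poisson train of
    difference-of-exponential inward events + tonic steps; after
    ``bicuculline_time_s`` every GABAergic component (events and tonic) is
    zeroed, leaving baseline + noise.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    t = np.arange(n) / config.fs_hz

    trace = np.full(n, config.baseline_pA)
    trace += rng.standard_normal(n) * config.noise_sd_pA

    bic_i = int(round(config.bicuculline_time_s * config.fs_hz))
    drug_i = int(round(config.drug_time_s * config.fs_hz))
    trace[:bic_i] += config.baseline_tonic_pA
    trace[drug_i:bic_i] += config.drug_tonic_shift_pA

    # Poisson event train, blocked after bicuculline
    if config.ipsc_rate_hz > 0:
        n_events = rng.poisson(config.ipsc_rate_hz * config.bicuculline_time_s)
        times = np.sort(rng.uniform(0, config.bicuculline_time_s, n_events))
    else:
        times = np.array([])
    amps, taus = [], []
    for t0 in times:
        amp = config.ipsc_amp_mean_pA * max(
            1 + config.ipsc_amp_cv * rng.standard_normal(), 0.05
        )
        tau = config.ipsc_tau_ms
        if t0 >= config.drug_time_s:
            amp *= config.drug_amp_gain
            tau *= config.drug_tau_gain
        kern = _ipsc_kernel(config.fs_hz, amp, tau, config.ipsc_rise_ms)
        i0 = int(round(t0 * config.fs_hz))
        i1 = min(i0 + len(kern), bic_i)  # block truncates decaying events
        trace[i0:i1] += kern[: i1 - i0]
        amps.append(-amp)
        taus.append(tau)

    patch = PatchTrace(
        current_pA=trace,
        fs_hz=config.fs_hz,
        markers={
            "drug_admin": config.drug_time_s,
            "bicuculline": config.bicuculline_time_s,
        },
        qc={"series_resistance_change_frac": 0.0, "capacitance_change_frac": 0.0},
    )
    truth = PatchGroundTruth(
        event_times_s=times,
        event_amps_pA=np.asarray(amps),
        event_taus_ms=np.asarray(taus),
        baseline_tonic_pA=config.baseline_tonic_pA,
        drug_tonic_shift_pA=config.drug_tonic_shift_pA,
        drug_time_s=config.drug_time_s,
        bicuculline_time_s=config.bicuculline_time_s,
    )
    return patch, truth


# ---------------------------------------------------------------------------
# Behavioral cohorts
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Cohort design for SIT / TST endpoints.

    Depressed mice have dSIT2/dSIT3 reduced by ``depression_drop_frac``
    relative to dSIT1; resilient mice do not drop.  Depressed mice are
    assigned round-robin to treatment arms; ``treatment_effects`` maps
    arm -> {day: additive recovery (s)} applied to post-drug SIT times.
    """

    n_mice: int = 39
    p_depressed: float = 0.7
    sit_base_s: float = 80.0
    depression_drop_frac: float = 0.5
    arms: tuple[str, ...] = ("vehicle", "diazepam", "allopregnanolone")
    treatment_effects: dict = field(
        default_factory=lambda: {
            "vehicle": {1: 0.0, 3: 0.0, 7: 0.0},
            "diazepam": {1: 0.0, 3: 0.0, 7: 0.0},
            "allopregnanolone": {1: 40.0, 3: 40.0, 7: 40.0},
        }
    )
    tst_immobility_base_s: float = 180.0
    tst_effects_s: dict = field(
        default_factory=lambda: {
            "vehicle": 0.0,
            "diazepam": 0.0,
            "allopregnanolone": -60.0,
        }
    )
    noise_sd_s: float = 15.0
    genotype: str = "WT"
    condition: str = "SDS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValidationError("n_mice must be >= 1")
        if not 0 <= self.p_depressed <= 1:
            raise ValidationError("p_depressed must lie in [0, 1]")
        if not 0 <= self.sit_base_s <= 150:
            raise ValidationError("sit_base_s outside the 150-s trial")
        if not 0 <= self.depression_drop_frac <= 1:
            raise ValidationError("depression_drop_frac must lie in [0, 1]")
        if self.noise_sd_s < 0:
            raise ValidationError("noise_sd_s must be >= 0")
        for arm in self.arms:
            if arm not in self.treatment_effects:
                raise ValidationError(f"no treatment effect declared for {arm!r}")


def _clip_sit(x):
    return np.clip(x, 0.0, 150.0)


def simulate_behavior_cohort(config: BehaviorSimConfig) -> pd.DataFrame:
    """Simulate per-mouse SIT/TST/OFT rows with a known depressed fraction.

    The returned table carries a ``depressed_true`` ground-truth column
    (which downstream classification ignores); post-drug SIT columns and
    TST immobility are populated for depressed mice only, mirroring the
    screen-then-treat design.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mice
    depressed = rng.uniform(size=n) < config.p_depressed
    noise = lambda size=n: rng.standard_normal(size) * config.noise_sd_s  # noqa: E731

    dsit1 = _clip_sit(config.sit_base_s + noise())
    keep = 1 - config.depression_drop_frac
    base23 = np.where(depressed, dsit1 * keep, dsit1 * 1.2)
    dsit2 = _clip_sit(base23 + noise())
    dsit3 = _clip_sit(base23 + noise())

    arm = np.full(n, np.nan, dtype=object)
    arm[depressed] = [
        config.arms[i % len(config.arms)] for i in range(int(depressed.sum()))
    ]

    rows = {
        "mouse_id": [f"m{i:03d}" for i in range(n)],
        "genotype": config.genotype,
        "condition": config.condition,
        "arm": arm,
        "dsit1_s": dsit1,
        "dsit2_s": dsit2,
        "dsit3_s": dsit3,
        "depressed_true": depressed,
    }
    sit_pre = dsit3.copy()
    rows["sit_pre_s"] = np.where(depressed, sit_pre, np.nan)
    for day in (1, 3, 7):
        vals = np.full(n, np.nan)
        for i in range(n):
            if depressed[i]:
                eff = config.treatment_effects[arm[i]].get(day, 0.0)
                vals[i] = float(
                    _clip_sit(sit_pre[i] + eff + rng.standard_normal() * config.noise_sd_s)
                )
        rows[f"sit_day{day}_s"] = vals

    tst = np.full(n, np.nan)
    for i in range(n):
        if depressed[i]:
            eff = config.tst_effects_s.get(arm[i], 0.0)
            tst[i] = float(
                np.clip(
                    config.tst_immobility_base_s + eff
                    + rng.standard_normal() * 2 * config.noise_sd_s,
                    0.0,
                    480.0,
                )
            )
    rows["tst_immobility_s"] = tst
    rows["oft_distance_m"] = np.clip(60 + rng.standard_normal(n) * 10, 0, None)
    rows["oft_center_s"] = np.clip(90 + rng.standard_normal(n) * 30, 0, 600)
    return pd.DataFrame(rows)
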