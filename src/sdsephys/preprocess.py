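"""Artifact exclusion and per-bin interpolation rules.

Signals are scored in half-open 1-s bins [t, t+1).  Two exclusion rules are
applied: an amplitude rule (any sample in the bin strictly exceeding 2 mV
in absolute value) and a movement rule (per-bin RMS of the 100-Hz
high-passed EMG strictly exceeding its session mean + 1 SD).  A recording
is analysable only if the union of excluded bins covers less than 10% of
the session.  Per-bin series are repaired over excluded bins by linear
interpolation between the nearest included neighbors, with constant
extension at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import UnitError, ValidationError
from .trace_io import TraceRecording

AMPLITUDE_THRESHOLD_MV = 2.0
MAX_EXCLUDED_FRACTION = 0.10
EMG_HIGHPASS_HZ = 100.0

REASON_AMPLITUDE = "amplitude"
REASON_EMG = "emg"
REASON_BOTH = "both"


@dataclass
class BinMask:
    """Per-1-s-bin exclusion vector with per-bin provenance."""

    excluded: np.ndarray          # bool, shape (n_bins,)
    reason: np.ndarray            # str, "" where included

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        if self.excluded.shape != self.reason.shape:
            raise ValidationError("excluded and reason must have equal length")
        bad = [(e, r) for e, r in zip(self.excluded, self.reason) if e != bool(r)]
        if bad:
            raise ValidationError("reason must be present iff a bin is excluded")

    @property
    def n_bins(self) -> int:
        return len(self.excluded)

    @property
    def excluded_fraction(self) -> float:
        return float(self.excluded.sum()) / self.n_bins

    @property
    def excluded_bins(self) -> np.ndarray:
        return np.flatnonzero(self.excluded)

    def to_intervals(self) -> list[tuple[float, float, str]]:
        """Contiguous excluded runs as (start_s, end_s, reason) for audit."""
        out = []
        i = 0
        while i < self.n_bins:
            if self.excluded[i]:
                j = i
                while (
                    j + 1 < self.n_bins
                    and self.excluded[j + 1]
                    and self.reason[j + 1] == self.reason[i]
                ):
                    j += 1
                out.append((float(i), float(j + 1), str(self.reason[i])))
                i = j + 1
            else:
                i += 1
        return out


@dataclass
class EmgFeature:
    """Per-bin RMS of the high-passed EMG and the mean+1SD threshold."""

    rms_per_bin: np.ndarray
    threshold: float


def _n_bins(rec: TraceRecording) -> int:
    return int(rec.n_samples // rec.fs_hz)


def _mask_from_bool(excluded: np.ndarray, reason: str) -> BinMask:
    reasons = np.array([reason if e else "" for e in excluded], dtype=object)
    return BinMask(excluded=excluded, reason=reasons)


def amplitude_mask(
    rec: TraceRecording,
    channel: str,
    threshold_mV: float = AMPLITUDE_THRESHOLD_MV,
) -> BinMask:
    """Exclude bins whose peak absolute amplitude strictly exceeds 2 mV."""
    if channel not in rec.channels:
        raise ValidationError(f"no channel {channel!r}")
    if rec.roles[channel] not in ("LFP", "EEG"):
        raise ValidationError(
            f"amplitude rule applies to LFP/EEG channels, not {rec.roles[channel]}"
        )
    if rec.units[channel] != "mV":
        raise UnitError(
            f"amplitude threshold is in mV but channel {channel!r} is in "
            f"{rec.units[channel]!r}"
        )
    nb = _n_bins(rec)
    fs = int(round(rec.fs_hz))
    x = np.abs(rec.channels[channel][: nb * fs]).reshape(nb, fs)
    excluded = x.max(axis=1) > threshold_mV
    return _mask_from_bool(excluded, REASON_AMPLITUDE)


def emg_mask(rec: TraceRecording) -> tuple[EmgFeature, BinMask]:
    """Exclude movement bins: rmsEMG strictly above its mean + 1 SD.

    The EMG channel is zero-phase high-passed at 100 Hz (4th-order
    Butterworth), RMS is taken per 1-s bin, and the threshold is computed
    over all bins of the session.
    """
    channel = rec.channel_by_role("EMG")
    if rec.fs_hz <= 2 * EMG_HIGHPASS_HZ:
        raise ValidationError(
            f"EMG sampling rate {rec.fs_hz} Hz too low for a 100-Hz high-pass"
        )
    sos = signal.butter(4, EMG_HIGHPASS_HZ, btype="highpass", fs=rec.fs_hz,
                        output="sos")
    x = signal.sosfiltfilt(sos, rec.channels[channel])
    nb = _n_bins(rec)
    fs = int(round(rec.fs_hz))
    rms = np.sqrt(np.mean(x[: nb * fs].reshape(nb, fs) ** 2, axis=1))
    threshold = float(rms.mean() + rms.std())
    excluded = rms > threshold
    return EmgFeature(rms_per_bin=rms, threshold=threshold), _mask_from_bool(
        excluded, REASON_EMG
    )


def combine_masks(*masks: BinMask) -> BinMask:
    """Union of exclusions; overlapping reasons merge to 'both'."""
    if not masks:
        raise ValidationError("need at least one mask")
    nb = masks[0].n_bins
    if any(m.n_bins != nb for m in masks):
        raise ValidationError("masks differ in length")
    excluded = np.zeros(nb, dtype=bool)
    reason = np.array([""] * nb, dtype=object)
    for m in masks:
        for i in np.flatnonzero(m.excluded):
            excluded[i] = True
            if reason[i] and reason[i] != m.reason[i]:
                reason[i] = REASON_BOTH
            elif not reason[i]:
                reason[i] = m.reason[i]
    return BinMask(excluded=excluded, reason=reason)


def check_inclusion(mask: BinMask, max_frac: float = MAX_EXCLUDED_FRACTION) -> bool:
    """A recording is analysable iff strictly less than 10% of bins are excluded."""
    return mask.excluded_fraction < max_frac


def interpolate_excluded(series: np.ndarray, mask: BinMask) -> np.ndarray:
    """Fill excluded bins by linear interpolation between included neighbors.

    Leading/trailing excluded runs take the nearest included value.
    Included bins are returned unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] != mask.n_bins:
        raise ValidationError(
            f"series length {len(series)} != mask length {mask.n_bins}"
        )
    included = ~mask.excluded
    if not included.any():
        raise ValidationError("all bins are excluded; nothing to interpolate from")
    idx = np.arange(mask.n_bins)
    out = series.copy()
    out[mask.excluded] = np.interp(
        idx[mask.excluded], idx[included], series[included]
    )
    return out
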