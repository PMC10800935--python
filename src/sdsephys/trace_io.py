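"""Reading and writing of time-series recordings and behavior tables.

Two interchange formats are supported for multichannel recordings:

* **EDF** (European Data Format, 16-bit): the standard exchange format for
  EEG/LFP.  Writing is implemented here (fixed-layout header + int16
  records); reading goes through :mod:`mne`, which also serves as an
  independent check that the files we emit are spec-conformant.
* **TSV + JSON sidecar**: lossless UTF-8 delimited text with a JSON sidecar
  carrying sampling rate, units, channel roles, event markers and subject
  metadata.

Patch-clamp current traces use the TSV + sidecar route only (proprietary
acquisition formats are out of scope).  Units are never implicit: every
channel carries its unit string and unit-sensitive operations refuse to run
on a mismatch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VOLTAGE_ROLES = ("LFP", "EEG", "EMG")
GENOTYPES = ("WT", "Gabrd-KO")
CONDITIONS = ("naive", "SDS")
ARMS = ("vehicle", "diazepam", "allopregnanolone", "escitalopram")


@dataclass
class TraceRecording:
    """A multichannel recording (LFP/EEG/EMG) with a common time origin.

    channels map channel name -> 1-D float array; all channels share
    ``fs_hz``.  ``markers`` are event times in seconds from recording start
    (e.g. ``drug_admin``).
    """

    channels: dict[str, np.ndarray]
    fs_hz: float
    units: dict[str, str]
    roles: dict[str, str]
    markers: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        if not self.channels:
            raise ValidationError("recording has no channels")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValidationError(f"channel length mismatch: {lengths}")
        for name in self.channels:
            if name not in self.units or name not in self.roles:
                raise ValidationError(f"channel {name!r} lacks units or role")
            if self.roles[name] not in VOLTAGE_ROLES:
                raise ValidationError(
                    f"channel {name!r} has unknown role {self.roles[name]!r}"
                )
        dur = self.duration_s
        for mname, t in self.markers.items():
            if not 0 <= t <= dur:
                raise ValidationError(
                    f"marker {mname!r} at {t} s outside recording [0, {dur}] s"
                )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_by_role(self, role: str) -> str:
        """Name of the unique channel with the given role.

        Raises ValidationError if absent or ambiguous — callers that need an
        EMG channel use this as their declared precondition check.
        """
        names = [n for n, r in self.roles.items() if r == role]
        if not names:
            raise ValidationError(f"recording has no channel with role {role!r}")
        if len(names) > 1:
            raise ValidationError(f"multiple channels with role {role!r}: {names}")
        return names[0]


@dataclass
class PatchTrace:
    """A whole-cell voltage-clamp current trace (pA, inward negative)."""

    current_pA: np.ndarray
    fs_hz: float
    markers: dict[str, float] = field(default_factory=dict)
    qc: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        for k, v in self.qc.items():
            if v < 0:
                raise ValidationError(f"qc fraction {k}={v} must be >= 0")

    @property
    def duration_s(self) -> float:
        return len(self.current_pA) / self.fs_hz


# ---------------------------------------------------------------------------
# EDF writing (16-bit), reading via mne
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _phys_limit(x: float) -> float:
    """Format-stable physical limit: round-trips through an 8-char field."""
    for prec in (6, 5, 4, 3):
        s = f"{x:.{prec}g}"
        if len(s) <= 8 and len(f"{-float(s):g}") <= 8:
            return float(s)
    raise FormatError(f"cannot encode physical limit {x}")


def write_edf(rec: TraceRecording, path: str | Path) -> Path:
    """Write a recording as plain EDF plus a JSON sidecar for metadata.

    EDF stores samples as int16 against per-channel physical ranges, so the
    round trip is exact only to the 16-bit quantization step.  The sidecar
    (``<path>.json``) carries markers, roles and subject metadata, which
    plain EDF has no field for.
    """
    path = Path(path)
    if abs(rec.fs_hz - round(rec.fs_hz)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(rec.fs_hz))
    n_records = math.ceil(rec.n_samples / fs)
    names = list(rec.channels)
    ns = len(names)

    phys_max, scaled = {}, {}
    for name in names:
        x = np.asarray(rec.channels[name], dtype=float)
        pad = n_records * fs - len(x)
        if pad:
            x = np.concatenate([x, np.zeros(pad)])
        pm = _phys_limit(max(np.max(np.abs(x)) * 1.0001, 1e-6))
        phys_max[name] = pm
        # EDF affine convention: physical = (digital - dmin) * cal + pmin
        cal = 2 * pm / 65535
        scaled[name] = np.clip(
            np.round((x + pm) / cal) - 32768, -32768, 32767
        ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(rec.meta.get("subject_id", "X"), 80))
        fh.write(_edf_field("sdsephys", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (1 + ns), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_records, 8))
        fh.write(_edf_field(1, 8))
        fh.write(_edf_field(ns, 4))
        for name in names:
            fh.write(_edf_field(name, 16))
        for _ in names:
            fh.write(_edf_field("", 80))
        for name in names:
            fh.write(_edf_field(rec.units[name], 8))
        for name in names:
            fh.write(_edf_field(f"{-phys_max[name]:g}", 8))
        for name in names:
            fh.write(_edf_field(f"{phys_max[name]:g}", 8))
        for _ in names:
            fh.write(_edf_field(-32768, 8))
        for _ in names:
            fh.write(_edf_field(32767, 8))
        for _ in names:
            fh.write(_edf_field("", 80))
        for _ in names:
            fh.write(_edf_field(fs, 8))
        for _ in names:
            fh.write(_edf_field("", 32))
        for r in range(n_records):
            for name in names:
                fh.write(scaled[name][r * fs : (r + 1) * fs].tobytes())

    sidecar = {
        "fs_hz": rec.fs_hz,
        "n_samples": rec.n_samples,
        "units": rec.units,
        "roles": rec.roles,
        "markers": rec.markers,
        "meta": rec.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_edf(path: str | Path) -> TraceRecording:
    """Read an EDF file (via mne) together with its JSON sidecar."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    units = sidecar.get("units", {})
    roles = sidecar.get("roles", {})
    channels = {}
    for i, name in enumerate(raw.ch_names):
        x = raw.get_data(picks=[i])[0]
        # mne rescales voltage dimensions to volts; undo to the declared unit
        unit = units.get(name, "mV")
        factor = {"V": 1.0, "mV": 1e3, "uV": 1e6}.get(unit, 1.0)
        channels[name] = x * factor
        units.setdefault(name, unit)
        roles.setdefault(name, "LFP")
    n = sidecar.get("n_samples")
    if n is not None:
        for name in channels:
            if len(channels[name]) < n:
                raise FormatError(
                    f"sidecar declares {n} samples but EDF holds "
                    f"{len(channels[name])}"
                )
            channels[name] = channels[name][:n]
    return TraceRecording(
        channels=channels,
        fs_hz=float(sidecar.get("fs_hz", raw.info["sfreq"])),
        units=units,
        roles=roles,
        markers=sidecar.get("markers", {}),
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# TSV + sidecar (lossless)
# ---------------------------------------------------------------------------

def write_recording_tsv(rec: TraceRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({name: rec.channels[name] for name in rec.channels})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    sidecar = {
        "fs_hz": rec.fs_hz,
        "n_samples": rec.n_samples,
        "units": rec.units,
        "roles": rec.roles,
        "markers": rec.markers,
        "meta": rec.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_tsv(path: str | Path) -> TraceRecording:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("fs_hz", "units", "roles"):
        if key not in sidecar:
            raise FormatError(f"sidecar lacks required key {key!r}")
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"{path} contains no samples")
    n_declared = sidecar.get("n_samples", len(df))
    if n_declared != len(df):
        raise FormatError(
            f"sidecar declares {n_declared} samples but file holds {len(df)}"
        )
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns}
    return TraceRecording(
        channels=channels,
        fs_hz=float(sidecar["fs_hz"]),
        units=sidecar["units"],
        roles=sidecar["roles"],
        markers=sidecar.get("markers", {}),
        meta=sidecar.get("meta", {}),
    )


def write_recording(rec: TraceRecording, path: str | Path, format: str = "auto") -> Path:
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if format == "edf":
        return write_edf(rec, path)
    if format == "tsv":
        return write_recording_tsv(rec, path)
    raise ValidationError(f"unknown recording format {format!r}")


def read_recording(path: str | Path, format: str = "auto") -> TraceRecording:
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if format == "edf":
        return read_edf(path)
    if format == "tsv":
        return read_recording_tsv(path)
    raise ValidationError(f"unknown recording format {format!r}")


def write_patch_trace(trace: PatchTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"current_pA": trace.current_pA}).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )
    sidecar = {
        "fs_hz": trace.fs_hz,
        "markers": trace.markers,
        "qc": trace.qc,
        "meta": trace.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_patch_trace(path: str | Path) -> PatchTrace:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "fs_hz" not in sidecar:
        raise FormatError("sidecar lacks required key 'fs_hz'")
    df = pd.read_csv(path, sep="\t")
    if "current_pA" not in df.columns or df.empty:
        raise FormatError(f"{path} has no 'current_pA' column")
    return PatchTrace(
        current_pA=df["current_pA"].to_numpy(dtype=float),
        fs_hz=float(sidecar["fs_hz"]),
        markers=sidecar.get("markers", {}),
        qc=sidecar.get("qc", {}),
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Behavior tables
# ---------------------------------------------------------------------------

SIT_TRIAL_S = 150.0
TST_SCORED_S = 480.0
OFT_CENTER_MAX_S = 600.0


def validate_behavior_table(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValidationError("behavior table is empty")
    if "mouse_id" not in df.columns:
        raise ValidationError("behavior table lacks a 'mouse_id' column")
    if df["mouse_id"].duplicated().any():
        dups = df.loc[df["mouse_id"].duplicated(), "mouse_id"].tolist()
        raise ValidationError(f"duplicate mouse ids: {dups}")
    sit_cols = [c for c in df.columns if c.startswith(("dsit", "sit_"))]
    for c in sit_cols:
        vals = df[c].dropna()
        if (vals < 0).any() or (vals > SIT_TRIAL_S).any():
            raise ValidationError(
                f"column {c!r} outside [0, {SIT_TRIAL_S}] s trial window"
            )
    if "tst_immobility_s" in df.columns:
        vals = df["tst_immobility_s"].dropna()
        if (vals < 0).any() or (vals > TST_SCORED_S).any():
            raise ValidationError("tst_immobility_s outside [0, 480] s")
    if "oft_center_s" in df.columns:
        vals = df["oft_center_s"].dropna()
        if (vals < 0).any() or (vals > OFT_CENTER_MAX_S).any():
            raise ValidationError("oft_center_s outside [0, 600] s")
    return df


def read_behavior_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path} is empty") from exc
    return validate_behavior_table(df)


def write_behavior_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def write_results(tables: dict[str, pd.DataFrame], summary: dict, outdir: str | Path) -> Path:
    """Write result tables as TSV and the scalar summary as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.9g")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return outdir
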