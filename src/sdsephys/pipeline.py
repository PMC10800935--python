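"""End-to-end orchestration: simulate -> preprocess -> analyze -> statistics.

A single :class:`RunConfig` drives a full simulated study: an LFP/EEG
cohort per treatment arm with the paper-style 60-min session and 30-min
drug mark, a patch-clamp cohort with per-arm tonic/synaptic drug effects,
and a behavioral cohort.  Every stage draws from a seed stream derived
from (seed, stage, subject), so disabling one stage never changes
another's output and identical seeds give byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, preprocess, spectral, stats, synth, trace_io
from . import patch as patchmod
from .errors import ValidationError

log = logging.getLogger("sdsephys")

_STAGE_KEY = {"lfp": 0, "patch": 1, "behavior": 2}


@dataclass
class RunConfig:
    """Study design constants plus simulation effect sizes, one per arm."""

    seed: int
    output_dir: str | None = None
    stages: tuple[str, ...] = ("lfp", "patch", "behavior")
    arms: tuple[str, ...] = ("vehicle", "diazepam", "allopregnanolone")
    n_mice_per_arm: int = 7
    # per-arm multiplicative amplitude gains applied at the drug mark
    band_gains: dict = field(
        default_factory=lambda: {
            "vehicle": {"theta": 1.0, "beta": 1.0},
            "diazepam": {"theta": 1.0, "beta": 1.2},
            "allopregnanolone": {"theta": 1.2, "beta": 1.2},
        }
    )
    lfp: dict = field(
        default_factory=lambda: {
            "duration_s": 3600.0,
            "fs_hz": 400.0,
            "channel_role": "EEG",
        }
    )
    n_cells_per_arm: int = 6
    # per-arm drug effects on the patch simulation
    tonic_shift_pA: dict = field(
        default_factory=lambda: {
            "vehicle": 0.0,
            "diazepam": 0.0,
            "allopregnanolone": -15.0,
        }
    )
    patch: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    amplitude_threshold_mV: float = preprocess.AMPLITUDE_THRESHOLD_MV
    max_excluded_fraction: float = preprocess.MAX_EXCLUDED_FRACTION
    qc_max_change_frac: float = patchmod.QC_MAX_CHANGE_FRAC

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for simulation runs")
        for arm in self.arms:
            if arm not in self.band_gains or arm not in self.tonic_shift_pA:
                raise ValidationError(f"no simulated effects declared for arm {arm!r}")
        unknown = set(self.stages) - set(_STAGE_KEY)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("stages", "arms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        path = Path(path)
        if not path.exists():
            raise ValidationError(f"no such config file: {path}")
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    summary: dict
    manifest: dict


def _sub_seed(seed: int, stage: str, index: int) -> int:
    ss = np.random.SeedSequence((seed, _STAGE_KEY[stage], index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _run_lfp_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rows, tests = [], []
    inclusion = {}
    idx = 0
    for arm in config.arms:
        gains = config.band_gains[arm]
        for m in range(config.n_mice_per_arm):
            sim = synth.LfpSimConfig(
                drug_band_gain=(gains["theta"], gains["beta"]),
                seed=_sub_seed(config.seed, "lfp", idx),
                **config.lfp,
            )
            rec, _ = synth.simulate_lfp_session(sim)
            sig = rec.channel_by_role(sim.channel_role)
            amp = preprocess.amplitude_mask(
                rec, sig, threshold_mV=config.amplitude_threshold_mV
            )
            _, emg = preprocess.emg_mask(rec)
            mask = preprocess.combine_masks(amp, emg)
            # the <10% analysability rule is stated for the 2-mV amplitude
            # exclusions; the movement mask always flags the upper rmsEMG
            # tail and is repaired by interpolation instead
            included = preprocess.check_inclusion(
                amp, max_frac=config.max_excluded_fraction
            )
            rec_id = f"{arm}-{m:02d}"
            inclusion[rec_id] = {
                "included": bool(included),
                "excluded_fraction": mask.excluded_fraction,
            }
            if not included:
                log.warning("recording %s excluded (%.1f%% masked)",
                            rec_id, 100 * mask.excluded_fraction)
                idx += 1
                continue
            spec = spectral.per_bin_spectrum(rec, sig)
            series = spectral.normalized_band_power(spec, mask=mask)
            row = {"recording": rec_id, "arm": arm,
                   "excluded_fraction": mask.excluded_fraction}
            for band in series.bands:
                pp = spectral.pre_post_summary(
                    series.bands[band], series.bin_times_s, sim.drug_time_s
                )
                row[f"{band}_pre"] = pp.pre_mean
                row[f"{band}_post"] = pp.post_mean
                row[f"{band}_post_over_pre"] = pp.post_over_pre
            rows.append(row)
            idx += 1
    df = pd.DataFrame(rows)
    for arm in config.arms:
        sub = df[df["arm"] == arm]
        for band in ("theta", "beta"):
            if len(sub) >= 2:
                r = stats.paired_t(
                    sub[f"{band}_pre"].to_numpy(),
                    sub[f"{band}_post"].to_numpy(),
                    comparison=f"{arm}: {band} post vs pre",
                )
                tests.append(r)
    tests_df = _tests_frame(tests)
    return df, tests_df, inclusion


def _run_patch_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, tests = [], []
    idx = 0
    for arm in config.arms:
        for c in range(config.n_cells_per_arm):
            sim = synth.PatchSimConfig(
                drug_tonic_shift_pA=config.tonic_shift_pA[arm],
                seed=_sub_seed(config.seed, "patch", idx),
                **config.patch,
            )
            trace, _ = synth.simulate_patch_trace(sim)
            if not patchmod.qc_cell(trace, max_change_frac=config.qc_max_change_frac):
                idx += 1
                continue
            pre, post = patchmod.pre_post_tonic(trace)
            drug, bic = trace.markers["drug_admin"], trace.markers["bicuculline"]
            pre_win = (drug - 30.0, drug)
            post_win = (bic - 30.0, bic)
            s_pre = patchmod.summarize_ipscs(patchmod.detect_ipscs(trace, pre_win), pre_win)
            s_post = patchmod.summarize_ipscs(patchmod.detect_ipscs(trace, post_win), post_win)
            rows.append({
                "cell": f"{arm}-{c:02d}", "arm": arm,
                "pretonic_pA": pre.tonic_pA, "posttonic_pA": post.tonic_pA,
                "potentiation_pA": patchmod.drug_tonic_potentiation(pre, post),
                "ipsc_amp_pre_pA": s_pre.mean_amplitude_pA,
                "ipsc_amp_post_pA": s_post.mean_amplitude_pA,
                "ipsc_freq_pre_hz": s_pre.frequency_hz,
                "ipsc_freq_post_hz": s_post.frequency_hz,
                "ipsc_tau_pre_ms": s_pre.mean_tau_ms,
                "ipsc_tau_post_ms": s_post.mean_tau_ms,
            })
            idx += 1
    df = pd.DataFrame(rows)
    for arm in config.arms:
        sub = df[df["arm"] == arm]
        if len(sub) >= 2:
            tests.append(stats.paired_t(
                sub["pretonic_pA"].to_numpy(), sub["posttonic_pA"].to_numpy(),
                comparison=f"{arm}: tonic post vs pre",
            ))
    return df, _tests_frame(tests)


def _run_behavior_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    sim = synth.BehaviorSimConfig(
        arms=config.arms,
        seed=_sub_seed(config.seed, "behavior", 0),
        **config.behavior,
    )
    table = synth.simulate_behavior_cohort(sim)
    frac = behavior.depressed_fraction(table)
    sit = behavior.sit_time_course(table)
    tst = behavior.treatment_effect_table(table, "tst")
    tests_df = _tests_frame(sit.tests + tst.tests)
    return table, tests_df, {"depressed_fraction": frac,
                             "sit_summary": sit.summary.to_dict("records")}


def _tests_frame(tests: list[stats.TestResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"method": t.method, "comparison": t.comparison,
         "statistic": t.statistic, "df": t.df,
         "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
         "significant": t.significant}
        for t in tests
    ])


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the configured stages and (optionally) write all outputs.

    Output tables are deterministic functions of the config (seed included);
    the manifest records the config, its hash and library versions so a run
    can be reproduced exactly.
    """
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": config.seed}
    inclusion: dict = {}

    if "lfp" in config.stages:
        log.info("stage lfp: %d arms x %d mice", len(config.arms), config.n_mice_per_arm)
        lfp_df, lfp_tests, inclusion = _run_lfp_stage(config)
        tables["lfp_band_power"] = lfp_df
        tables["lfp_tests"] = lfp_tests
        summary["lfp"] = {
            "n_recordings": len(inclusion),
            "n_included": sum(v["included"] for v in inclusion.values()),
            "post_over_pre_by_arm": {
                arm: {
                    band: float(
                        lfp_df.loc[lfp_df["arm"] == arm, f"{band}_post_over_pre"].mean()
                    )
                    for band in ("theta", "beta")
                }
                for arm in config.arms
                if (lfp_df["arm"] == arm).any()
            },
        }
    if "patch" in config.stages:
        log.info("stage patch: %d arms x %d cells", len(config.arms), config.n_cells_per_arm)
        patch_df, patch_tests = _run_patch_stage(config)
        tables["patch_cells"] = patch_df
        tables["patch_tests"] = patch_tests
        summary["patch"] = {
            "potentiation_by_arm": {
                arm: float(patch_df.loc[patch_df["arm"] == arm, "potentiation_pA"].mean())
                for arm in config.arms
                if (patch_df["arm"] == arm).any()
            }
        }
    if "behavior" in config.stages:
        log.info("stage behavior")
        beh_table, beh_tests, beh_summary = _run_behavior_stage(config)
        tables["behavior_cohort"] = beh_table
        tables["behavior_tests"] = beh_tests
        summary["behavior"] = {"depressed_fraction": beh_summary["depressed_fraction"]}

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": _versions(),
        "inclusion": inclusion,
    }
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        trace_io.write_results(tables, summary, outdir)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )
    return RunReport(tables=tables, summary=summary, manifest=manifest)


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"sdsephys": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
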