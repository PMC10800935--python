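"""Depression-like classification and SIT/TST/OFT outcome summaries.

A mouse is depression-like iff its interaction time dropped in both
post-defeat social interaction tests relative to the pre-defeat one:
dSIT2 < dSIT1 and dSIT3 < dSIT1 (strict; ties are not depression-like).
Treatment outcomes are summarized per arm and day with the designated
family of tests: Tukey for >= 3 arms, Sidak-adjusted unpaired t for two
arms (SIT time courses), Dunnett versus vehicle for single-timepoint
endpoints (TST, OFT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats
from .errors import ValidationError
from .trace_io import SIT_TRIAL_S

SIT_DAYS = (1, 3, 7)


def classify_depression(dsit1_s: float, dsit2_s: float, dsit3_s: float) -> bool:
    """True iff dSIT2 and dSIT3 are both strictly lower than dSIT1."""
    for name, v in (("dSIT1", dsit1_s), ("dSIT2", dsit2_s), ("dSIT3", dsit3_s)):
        if not 0 <= v <= SIT_TRIAL_S:
            raise ValidationError(
                f"{name} = {v} s outside the [0, {SIT_TRIAL_S}] s trial"
            )
    return dsit2_s < dsit1_s and dsit3_s < dsit1_s


def classify_table(table: pd.DataFrame) -> pd.Series:
    """Apply the classifier row-wise to a behavior table."""
    for col in ("dsit1_s", "dsit2_s", "dsit3_s"):
        if col not in table.columns:
            raise ValidationError(f"behavior table lacks column {col!r}")
    return table.apply(
        lambda r: classify_depression(r["dsit1_s"], r["dsit2_s"], r["dsit3_s"]),
        axis=1,
    )


def depressed_fraction(table: pd.DataFrame) -> float:
    return float(classify_table(table).mean())


@dataclass
class EndpointAnalysis:
    """Per-arm summaries and the designated group tests for one endpoint."""

    endpoint: str
    summary: pd.DataFrame                       # arm, day, n, mean, sem
    tests: list["_stats.TestResult"] = field(default_factory=list)


def _summarize(df: pd.DataFrame, value_col: str, by: list[str]) -> pd.DataFrame:
    g = df.groupby(by, sort=True)[value_col]
    out = g.agg(n="count", mean="mean", sem="sem").reset_index()
    return out


def sit_time_course(table: pd.DataFrame, days=SIT_DAYS) -> EndpointAnalysis:
    """Arm-by-day SIT analysis.

    Two arms: per-day unpaired t with Sidak adjustment across days.
    Three or more arms: per-day Tukey over all pairwise arm contrasts.
    """
    df = table.dropna(subset=["arm"]).copy()
    arms = sorted(df["arm"].unique())
    if len(arms) < 2:
        raise ValidationError("need at least two treatment arms")
    long = []
    for day in ("pre",) + tuple(days):
        col = "sit_pre_s" if day == "pre" else f"sit_day{day}_s"
        if col not in df.columns:
            raise ValidationError(f"table lacks column {col!r}")
        for arm in arms:
            vals = df.loc[df["arm"] == arm, col].dropna()
            if day != "pre" and len(vals) < 2:
                raise ValidationError(f"arm {arm!r} has fewer than two mice")
            long.append(pd.DataFrame({"arm": arm, "day": str(day), "value": vals}))
    long = pd.concat(long, ignore_index=True)
    summary = _summarize(long, "value", ["day", "arm"])

    def _vals(day, arm):
        sel = (long["day"] == str(day)) & (long["arm"] == arm)
        return long.loc[sel, "value"].to_numpy()

    tests: list[_stats.TestResult] = []
    if len(arms) == 2:
        raws = [
            _stats.unpaired_t(
                _vals(day, arms[0]), _vals(day, arms[1]),
                comparison=f"day {day}: {arms[0]} vs {arms[1]}",
            )
            for day in days
        ]
        adj = _stats.sidak([r.p_raw for r in raws])
        for r, p in zip(raws, adj):
            r.method = "sidak"
            r.p_adjusted = float(p)
            tests.append(r)
    else:
        for day in days:
            groups = [_vals(day, arm) for arm in arms]
            for r in _stats.tukey_hsd(*groups, labels=list(arms)):
                r.comparison = f"day {day}: {r.comparison}"
                tests.append(r)
    return EndpointAnalysis(endpoint="sit", summary=summary, tests=tests)


def single_endpoint(
    table: pd.DataFrame,
    value_col: str,
    control_arm: str = "vehicle",
) -> EndpointAnalysis:
    """Dunnett comparison of each treatment arm against the control arm."""
    df = table.dropna(subset=["arm", value_col]).copy()
    arms = sorted(df["arm"].unique())
    if control_arm not in arms:
        raise ValidationError(f"control arm {control_arm!r} not in table")
    treats = [a for a in arms if a != control_arm]
    if not treats:
        raise ValidationError("need at least one treatment arm besides control")
    control = df.loc[df["arm"] == control_arm, value_col].to_numpy()
    groups = [df.loc[df["arm"] == a, value_col].to_numpy() for a in treats]
    tests = _stats.dunnett(control, *groups, labels=treats)
    summary = _summarize(df, value_col, ["arm"])
    return EndpointAnalysis(endpoint=value_col, summary=summary, tests=tests)


def treatment_effect_table(
    table: pd.DataFrame, endpoint: str = "sit"
) -> EndpointAnalysis:
    """Dispatch to the endpoint's designated analysis."""
    if endpoint == "sit":
        return sit_time_course(table)
    if endpoint == "tst":
        return single_endpoint(table, "tst_immobility_s")
    if endpoint == "oft_distance":
        return single_endpoint(table, "oft_distance_m")
    if endpoint == "oft_center":
        return single_endpoint(table, "oft_center_s")
    raise ValidationError(f"unknown endpoint {endpoint!r}")
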