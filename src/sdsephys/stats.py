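"""Group-comparison statistics: paired/unpaired t, Tukey, Sidak, Dunnett.

Thin, explicit wrappers around scipy with a uniform :class:`TestResult`
record.  The unpaired t uses the Welch correction by default; all tests are
two-sided at alpha = 0.05.  Tukey's HSD is computed from Tukey–Kramer q
statistics against the studentized-range distribution; Dunnett's test
delegates to scipy's multivariate-t implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .errors import ValidationError

ALPHA = 0.05


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    comparison: str = ""
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha


def _as_1d(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"{name} must be 1-D")
    return x


def paired_t(x_pre, x_post, comparison: str = "post vs pre") -> TestResult:
    """Two-sided paired t-test on per-subject (pre, post) pairs."""
    a = _as_1d(x_pre, "x_pre")
    b = _as_1d(x_post, "x_post")
    if len(a) != len(b):
        raise ValidationError("paired samples must have equal length")
    if len(a) < 2:
        raise ValidationError("need at least two pairs")
    d = b - a
    if np.std(d) == 0:
        if d[0] == 0:  # identical samples: no effect, by convention t=0, p=1
            return TestResult(
                method="paired_t", statistic=0.0, df=float(len(d) - 1),
                p_raw=1.0, p_adjusted=1.0, comparison=comparison,
            )
        raise ValidationError("differences have zero variance; t is undefined")
    res = sst.ttest_rel(b, a)
    return TestResult(
        method="paired_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        comparison=comparison,
    )


def unpaired_t(a, b, welch: bool = True, comparison: str = "a vs b") -> TestResult:
    """Two-sided unpaired t-test (Welch by default)."""
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least two observations per group")
    res = sst.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        method="unpaired_t" + ("_welch" if welch else ""),
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        comparison=comparison,
    )


def sidak(p_raw, m: int | None = None):
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m.

    Accepts a scalar with explicit ``m``, or a sequence (m defaults to its
    length).
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if m is None:
        if p.ndim == 0:
            raise ValidationError("scalar input requires an explicit m")
        m = p.size
    if m < 1:
        raise ValidationError("m must be >= 1")
    adj = 1.0 - (1.0 - p) ** m
    return float(adj) if np.ndim(p_raw) == 0 else adj


def _tukey_q(groups: list[np.ndarray]):
    """Tukey–Kramer q statistic per pairwise contrast, plus df and labels."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(ns.sum() - k)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    qs, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
            qs.append(abs(means[i] - means[j]) / se)
            pairs.append((i, j))
    return np.array(qs), df, pairs


def tukey_hsd(*groups, labels: list[str] | None = None) -> list[TestResult]:
    """Tukey's HSD over all pairwise contrasts (Tukey–Kramer for unequal n)."""
    gs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(gs) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ValidationError("every group needs at least two observations")
    labels = labels or [f"g{i}" for i in range(len(gs))]
    qs, df, pairs = _tukey_q(gs)
    ps = sst.studentized_range.sf(qs, len(gs), df)
    return [
        TestResult(
            method="tukey",
            statistic=float(q),
            df=float(df),
            p_raw=float(p),
            p_adjusted=float(p),
            comparison=f"{labels[i]} vs {labels[j]}",
        )
        for q, p, (i, j) in zip(qs, ps, pairs)
    ]


def tukey_critical_q(k: int, df: int, alpha: float = ALPHA) -> float:
    """Studentized-range critical value: the family rejects iff max q exceeds it."""
    return float(sst.studentized_range.ppf(1 - alpha, k, df))


def dunnett(control, *treatments, labels: list[str] | None = None) -> list[TestResult]:
    """Dunnett's many-to-one comparisons against a control group."""
    c = _as_1d(control, "control")
    ts = [_as_1d(t, f"treatment {i}") for i, t in enumerate(treatments)]
    if not ts:
        raise ValidationError("need at least one treatment group")
    if len(c) < 2 or any(len(t) < 2 for t in ts):
        raise ValidationError("every group needs at least two observations")
    labels = labels or [f"t{i}" for i in range(len(ts))]
    # the multivariate-t integral is evaluated by randomized QMC; fix its
    # stream so identical inputs give identical adjusted p-values
    res = sst.dunnett(*ts, control=c, rng=np.random.default_rng(0))
    df = float(len(c) + sum(len(t) for t in ts) - (len(ts) + 1))
    return [
        TestResult(
            method="dunnett",
            statistic=float(res.statistic[i]),
            df=df,
            p_raw=float(res.pvalue[i]),
            p_adjusted=float(res.pvalue[i]),
            comparison=f"{labels[i]} vs control",
        )
        for i in range(len(ts))
    ]
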