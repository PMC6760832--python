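"""Error metrics, recovery statistics and model-comparison tests.

``rmse`` implements the single error formula shared by RMSEC (calibration/
autoprediction), RMSEP (independent test set) and the per-fold pieces of
RMSECV: sqrt(Σ(taken − found)²/N).  Recovery is 100·found/taken per sample.
Summary tables report the mean recovery, its standard deviation (population
form, divisor N, by default — the convention the reference tables follow) and
the RMSE.

The comparison machinery (pooled two-sample t, variance-ratio F, one-way
ANOVA) returns the statistic together with its critical value at p = 0.05
(two-tailed t, upper-tail F), matching standard method-comparison reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ShapeMismatchError, ValidationError


def _pair(taken, found):
    t = np.asarray(taken, dtype=float).ravel()
    f = np.asarray(found, dtype=float).ravel()
    if t.size != f.size:
        raise ShapeMismatchError(f"taken has {t.size} values, found has {f.size}")
    if t.size < 1:
        raise ShapeMismatchError("need at least one value")
    return t, f


def rmse(taken, found) -> float:
    """Root mean square error sqrt(Σ(taken−found)²/N)."""
    t, f = _pair(taken, found)
    return float(np.sqrt(np.mean((t - f) ** 2)))


def recovery_percent(taken, found) -> np.ndarray:
    """Per-sample percent recovery, 100·found/taken."""
    t, f = _pair(taken, found)
    if np.any(t <= 0):
        raise ValidationError("taken concentrations must be strictly positive")
    return 100.0 * f / t


@dataclass
class EvaluationReport:
    """Per-sample recoveries with summary statistics for one model/split."""

    sample_ids: list[str]
    taken: np.ndarray
    found: np.ndarray
    recovery_percent: np.ndarray
    mean_recovery: float
    sd_recovery: float
    rmse: float
    role: str  # "calibration" | "prediction"


def summarize(
    taken, found, role: str = "prediction", sample_ids=None, ddof: int = 0
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` (SD divisor N by default; ddof=1 for N−1)."""
    t, f = _pair(taken, found)
    rec = recovery_percent(t, f)
    ids = (
        [str(s) for s in sample_ids]
        if sample_ids is not None
        else [f"s{i + 1}" for i in range(t.size)]
    )
    if len(ids) != t.size:
        raise ShapeMismatchError("sample_ids length mismatch")
    return EvaluationReport(
        sample_ids=ids,
        taken=t,
        found=f,
        recovery_percent=rec,
        mean_recovery=float(np.mean(rec)),
        sd_recovery=float(np.std(rec, ddof=ddof)),
        rmse=rmse(t, f),
        role=role,
    )


@dataclass
class TestResult:
    """A test statistic with its critical value at the chosen significance level."""

    statistic: float
    critical_value: float
    df: tuple
    p_value: float | None = None

    @property
    def significant(self) -> bool:
        return self.statistic > self.critical_value


def two_sample_t(a, b, alpha: float = 0.05) -> TestResult:
    """Pooled-variance two-sample t test with its two-tailed critical value."""
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size < 2 or bv.size < 2:
        raise DegenerateDataError("both groups need ≥2 values")
    na, nb = av.size, bv.size
    df = na + nb - 2
    sp2 = ((na - 1) * av.var(ddof=1) + (nb - 1) * bv.var(ddof=1)) / df
    diff = av.mean() - bv.mean()
    if sp2 <= 0:
        stat = 0.0 if diff == 0 else math.inf
    else:
        stat = abs(diff) / math.sqrt(sp2 * (1 / na + 1 / nb))
    crit = float(stats.t.ppf(1 - alpha / 2, df))
    return TestResult(float(stat), crit, (df,))


def f_ratio(a, b, alpha: float = 0.05) -> TestResult:
    """Variance-ratio F test (larger/smaller) with its upper-tail critical value."""
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    if av.size < 2 or bv.size < 2:
        raise DegenerateDataError("both groups need ≥2 values")
    va, vb = av.var(ddof=1), bv.var(ddof=1)
    if va >= vb:
        num, den, dfn, dfd = va, vb, av.size - 1, bv.size - 1
    else:
        num, den, dfn, dfd = vb, va, bv.size - 1, av.size - 1
    if den <= 0:
        stat = 1.0 if num <= 0 else math.inf
    else:
        stat = num / den
    crit = float(stats.f.ppf(1 - alpha, dfn, dfd))
    return TestResult(float(stat), crit, (dfn, dfd))


def one_way_anova(groups, alpha: float = 0.05) -> TestResult:
    """One-way ANOVA F with p-value and upper-tail critical value."""
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise DegenerateDataError("need ≥2 groups with ≥2 values each")
    all_vals = np.concatenate(gs)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df_between = len(gs) - 1
    df_within = all_vals.size - len(gs)
    ms_between = ss_between / df_between
    if ss_within <= 0:
        stat = 0.0 if ss_between <= 0 else math.inf
        p = 1.0 if stat == 0.0 else 0.0
    else:
        stat = ms_between / (ss_within / df_within)
        p = float(stats.f.sf(stat, df_between, df_within))
    crit = float(stats.f.ppf(1 - alpha, df_between, df_within))
    return TestResult(float(stat), crit, (df_between, df_within), p_value=p)
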