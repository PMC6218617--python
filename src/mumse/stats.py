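"""Group-level statistics: t-tests with Cohen's d, Bonferroni control,
single-predictor OLS models of desynchronization, and the correlation of
percent changes.

t-tests and OLS are delegated to scipy.stats/statsmodels; what this module
adds is the bookkeeping the analysis needs — effect sizes, the corrected
threshold, the reporting structure (coefficient/SE pairs, R², residual RMSE,
degrees of freedom) and the t-statistic of a Pearson correlation,
t = r * sqrt(n-2) / sqrt(1-r²) with df = n-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's derived measures, one row of the group table.

    Keyed maps: desync by electrode; avg entropies by (electrode, band) per
    condition; global efficiency by band per condition; C3 clustering
    coefficient per condition.  Missing entries are simply absent keys.
    """

    subject: str
    desync: dict[str, float] = field(default_factory=dict)
    rest_entropy: dict[tuple[str, str], float] = field(default_factory=dict)
    task_entropy: dict[tuple[str, str], float] = field(default_factory=dict)
    rest_ge: dict[str, float] = field(default_factory=dict)
    task_ge: dict[str, float] = field(default_factory=dict)
    rest_cc_c3: float | None = None
    task_cc_c3: float | None = None
    rest_mu_power: float | None = None


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into a wide table (one row per subject)."""
    rows = []
    for rec in records:
        row: dict[str, float | str | None] = {"subject": rec.subject}
        for el, v in rec.desync.items():
            row[f"desync_{el}"] = v
        for (el, band), v in rec.rest_entropy.items():
            row[f"rest_entropy_{el}_{band}"] = v
        for (el, band), v in rec.task_entropy.items():
            row[f"task_entropy_{el}_{band}"] = v
        for band, v in rec.rest_ge.items():
            row[f"rest_ge_{band}"] = v
        for band, v in rec.task_ge.items():
            row[f"task_ge_{band}"] = v
        row["rest_cc_C3"] = rec.rest_cc_c3
        row["task_cc_C3"] = rec.task_cc_c3
        row["rest_mu_power"] = rec.rest_mu_power
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


@dataclass(frozen=True)
class TestResult:
    """t-statistic, degrees of freedom, two-sided p, Cohen's d, label."""

    statistic: float
    df: int
    p: float
    effect_size: float
    label: str = ""

    def __str__(self) -> str:  # paper-style rounding; full precision in fields
        return (f"{self.label}: t({self.df}) = {self.statistic:.3f}, "
                f"p = {self.p:.3f}, d = {self.effect_size:.3f}")


def one_sample_t(values: Sequence[float], mu0: float = 0.0, label: str = "") -> TestResult:
    """Two-sided one-sample t-test with Cohen's d = |mean - mu0| / SD."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(arr).all():
        raise ValueError("values contain non-finite entries")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t-statistic undefined")
    res = sps.ttest_1samp(arr, mu0)
    d = abs(arr.mean() - mu0) / sd
    return TestResult(float(res.statistic), int(arr.size - 1), float(res.pvalue), d, label)


def paired_t(rest_values: Sequence[float], task_values: Sequence[float],
             label: str = "") -> TestResult:
    """Paired t-test as a one-sample test on task - rest differences."""
    rest = np.asarray(rest_values, dtype=np.float64)
    task = np.asarray(task_values, dtype=np.float64)
    if rest.shape != task.shape:
        raise ValueError(f"length mismatch: {rest.shape} vs {task.shape}")
    return one_sample_t(task - rest, 0.0, label)


class BonferroniThreshold(NamedTuple):
    """Corrected per-comparison alpha, full precision and 3-decimal rounding."""

    threshold: float
    rounded: float


def bonferroni(alpha: float, k: int) -> BonferroniThreshold:
    """Bonferroni-corrected significance threshold alpha / k."""
    if k < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {k}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = alpha / k
    return BonferroniThreshold(t, round(t, 3))


@dataclass(frozen=True)
class RegressionResult:
    """Single-predictor OLS summary in the reporting layout of the analysis:
    coefficient (SE) pairs, R², residual RMSE and residual df."""

    predictor: str
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    slope_p: float
    r_squared: float
    rmse: float
    df: int
    f_statistic: float
    f_p: float


#: predictor selectors for the three desynchronization models
PREDICTOR_COLUMNS = {
    "rest_entropy": "rest_entropy_C3_alpha",   # model 1: baseline complexity
    "task_entropy": "task_entropy_C3_alpha",   # model 2: task complexity
    "rest_power": "rest_mu_power",             # model 3: baseline mu power
}


def regress_desync_on_baseline(
    records: Sequence[SubjectRecord] | pd.DataFrame,
    predictor: str = "rest_entropy",
    outcome: str = "desync_C3",
) -> RegressionResult:
    """OLS of the C3 desynchronization score on one subject-level predictor.

    ``predictor`` is one of ``rest_entropy`` (baseline complexity, the primary
    model), ``task_entropy`` or ``rest_power``, or any column name of the
    record table.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    column = PREDICTOR_COLUMNS.get(predictor, predictor)
    if column not in frame.columns:
        raise KeyError(f"predictor column {column!r} not in record table")
    if outcome not in frame.columns:
        raise KeyError(f"outcome column {outcome!r} not in record table")
    sub = frame[[column, outcome]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need at least 3 complete subjects, have {len(sub)}")
    x = sub[column].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {column!r} is constant; model unidentifiable")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    rmse = math.sqrt(fit.ssr / fit.df_resid)
    return RegressionResult(
        predictor=column,
        intercept=float(fit.params[0]), intercept_se=float(fit.bse[0]),
        slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
        slope_p=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared), rmse=rmse, df=int(fit.df_resid),
        f_statistic=float(fit.fvalue), f_p=float(fit.f_pvalue),
    )


class CorrelationResult(NamedTuple):
    r: float
    t: float
    df: int
    p: float


def corr_change(entropy_pct_change: Sequence[float],
                ge_pct_change: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of two percent-change vectors with its t-statistic.

    t = r sqrt(n-2) / sqrt(1 - r²), df = n - 2, two-sided p.
    """
    x = np.asarray(entropy_pct_change, dtype=np.float64)
    y = np.asarray(ge_pct_change, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r, t, df, p)
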