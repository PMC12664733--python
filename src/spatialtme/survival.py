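"""Survival estimation and the cohort-level statistical tests.

Kaplan-Meier product-limit estimation, two-group log-rank comparison and
univariable Cox proportional-hazards regression (Efron tie handling) are
delegated to :mod:`lifelines`; Mann-Whitney U, Fisher's exact test and
Pearson's chi-square to :mod:`scipy.stats`. All tests are two-sided at
α = 0.05 with no multiplicity correction.

Both Fisher's exact test and the chi-square test are exposed for 2×2
tables. Their p-values can differ appreciably at n = 80, so cohort reports
print both rather than silently choosing one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .exceptions import UsageError, ValidationError


@dataclass
class TestResult:
    """Outcome of a two-sided hypothesis test.

    ``method`` tags the procedure (``logrank``, ``fisher_exact``,
    ``chi_square``, ``mann_whitney``, ``cox``). Cox results additionally
    carry the hazard ratio with its Wald 95% CI.
    """

    statistic: float
    p: float
    method: str
    hr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    converged: bool = True
    extra: dict = field(default_factory=dict)


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit estimate of recurrence-free survival.

    ``times`` are the distinct event times, ``survival`` the step-function
    values S(t) just after each, ``at_risk`` the risk-set sizes.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): value of the step function at time t (1.0 before any event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def survival_at_60(self) -> float:
        """Five-year survival as a percentage (S at 60 months × 100)."""
        return 100.0 * self.survival_at(60.0)


def _check_surv(times, events):
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if times.size == 0:
        raise UsageError("empty survival record set")
    if times.shape != events.shape:
        raise UsageError("times and events must align")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    return times, events


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KmCurve:
    """Product-limit survival estimate; censoring handled at its time."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.asarray(sorted(set(times[events])))
    if event_times.size:
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        at_risk = np.array([(times >= t).sum() for t in event_times])
    else:
        surv = np.array([])
        at_risk = np.array([], dtype=int)
    return KmCurve(times=event_times, survival=surv, at_risk=at_risk,
                   n=len(times), n_events=int(events.sum()))


def logrank_test(times_a, events_a, times_b, events_b) -> TestResult:
    """Standard two-group log-rank chi-square test (1 df, two-sided)."""
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise UsageError("log-rank test needs at least one event across groups")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(statistic=float(res.test_statistic), p=float(res.p_value),
                      method="logrank")


def cox_fit(records: pd.DataFrame, covariate: str,
            duration_col: str = "rfs_months",
            event_col: str = "event") -> TestResult:
    """Univariable Cox proportional-hazards fit (Efron tie handling).

    Returns the Wald test on the coefficient with HR and 95% CI. Monotone
    likelihood (complete separation) is flagged as ``converged = False``
    with no HR reported rather than raising.
    """
    vals = records[covariate]
    if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
        levels = sorted(vals.dropna().unique())
        if len(levels) != 2:
            raise UsageError(f"categorical covariate {covariate!r} must have "
                             f"exactly 2 levels, got {levels}")
        records = records.copy()
        records[covariate] = (vals == levels[-1]).astype(float)
    if records[covariate].nunique() < 2:
        raise UsageError(f"covariate {covariate!r} does not vary")
    if records[event_col].sum() < 1:
        raise UsageError("Cox fit needs at least one event")
    df = records[[duration_col, event_col, covariate]].dropna().copy()
    df[event_col] = df[event_col].astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        return TestResult(statistic=np.nan, p=np.nan, method="cox",
                          converged=False)
    beta = float(cph.params_[covariate])
    se = float(cph.standard_errors_[covariate])
    if not np.isfinite(se) or se > 1e3:
        return TestResult(statistic=np.nan, p=np.nan, method="cox",
                          converged=False)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return TestResult(statistic=z, p=float(p), method="cox",
                      hr=float(np.exp(beta)), ci_low=float(np.exp(lo)),
                      ci_high=float(np.exp(hi)),
                      extra={"beta": beta, "se": se,
                             "n": len(df), "n_events": int(df[event_col].sum())})


def _check_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2) and t.ndim != 2:
        raise UsageError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValidationError("contingency table must hold integer counts")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValidationError("negative count in contingency table")
    return t


def fisher_exact_test(table) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 table.

    Two-sided p = sum of hypergeometric probabilities of tables at least as
    extreme (probability ≤ that of the observed table), the classical
    convention.
    """
    t = _check_table(table)
    if t.shape != (2, 2):
        raise UsageError("Fisher exact test requires a 2×2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), method="fisher_exact")


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    t = _check_table(table)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / max(t.sum(), 1)
    if (expected <= 0).any():
        raise UsageError("chi-square test requires all expected counts > 0")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method="chi_square")


def mann_whitney_test(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is ≤ 20 with no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise UsageError("Mann-Whitney test requires two non-empty samples")
    combined = np.concatenate([a, b])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return TestResult(statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
                      method="mann_whitney",
                      extra={"exact": exact})


def km_split_analysis(clinical: pd.DataFrame, labels: pd.Series,
                      duration_col: str = "rfs_months",
                      event_col: str = "event") -> dict:
    """KM curves, log-rank and Cox HR for a HIGH/LOW median split.

    Returns a dict with per-group :class:`KmCurve` (keys ``km_high``,
    ``km_low``), the log-rank :class:`TestResult`, the Cox result for
    LOW vs HIGH (HR > 1 means the LOW group fares worse), and the
    5-year survival percentage of each group.
    """
    df = clinical.set_index("case_id") if "case_id" in clinical.columns else clinical
    df = df.loc[df.index.intersection(labels.index)].copy()
    df["_group"] = labels.reindex(df.index)
    hi = df[df["_group"] == "HIGH"]
    lo = df[df["_group"] == "LOW"]
    if len(hi) == 0 or len(lo) == 0:
        raise UsageError("both split groups must be non-empty")
    km_hi = km_estimate(hi[duration_col], hi[event_col])
    km_lo = km_estimate(lo[duration_col], lo[event_col])
    lr = logrank_test(hi[duration_col], hi[event_col],
                      lo[duration_col], lo[event_col])
    cox_df = df.reset_index()[[duration_col, event_col]].copy()
    cox_df["low_group"] = (df["_group"] == "LOW").astype(float).to_numpy()
    cox = cox_fit(cox_df, "low_group", duration_col, event_col)
    return {"km_high": km_hi, "km_low": km_lo, "logrank": lr, "cox_low_vs_high": cox,
            "rfs60_high": km_hi.survival_at_60, "rfs60_low": km_lo.survival_at_60,
            "n_high": len(hi), "n_low": len(lo)}


def build_clinicopath_table(clinical: pd.DataFrame, labels: pd.Series,
                            categorical_vars: Sequence[str] = (),
                            continuous_vars: Sequence[str] = ()) -> pd.DataFrame:
    """Per-variable group composition table with statistical tests.

    For each categorical variable: per-group level counts and column
    percentages, plus a chi-square p-value and (for 2-level variables) a
    Fisher exact p-value. For each continuous variable: per-group median
    (IQR) plus a Mann-Whitney p-value. Cases without a group label are
    dropped with a warning; single-level variables are reported without a
    test.
    """
    df = clinical.set_index("case_id") if "case_id" in clinical.columns else clinical
    dropped = df.index.difference(labels.index)
    if len(dropped):
        warnings.warn(f"{len(dropped)} case(s) without a group label dropped")
    df = df.loc[df.index.intersection(labels.index)].copy()
    grp = labels.reindex(df.index)
    hi, lo = df[grp == "HIGH"], df[grp == "LOW"]
    rows = []
    for var in categorical_vars:
        levels = sorted(df[var].dropna().unique())
        counts = np.array([[(hi[var] == lv).sum(), (lo[var] == lv).sum()]
                           for lv in levels])
        p_chi = p_fisher = np.nan
        if len(levels) >= 2:
            p_chi = chi_square_test(counts.T).p
            if len(levels) == 2:
                p_fisher = fisher_exact_test(counts.T).p
        else:
            warnings.warn(f"variable {var!r} has a single level; test skipped")
        for i, lv in enumerate(levels):
            rows.append({
                "variable": var, "level": lv,
                "n_high": int(counts[i, 0]),
                "pct_high": 100.0 * counts[i, 0] / max(len(hi), 1),
                "n_low": int(counts[i, 1]),
                "pct_low": 100.0 * counts[i, 1] / max(len(lo), 1),
                "p_chi_square": p_chi if i == 0 else np.nan,
                "p_fisher": p_fisher if i == 0 else np.nan,
                "p_mann_whitney": np.nan,
            })
    for var in continuous_vars:
        a, b = hi[var].dropna(), lo[var].dropna()
        p_mw = mann_whitney_test(a, b).p if len(a) and len(b) else np.nan
        for name, s in (("HIGH", a), ("LOW", b)):
            q1, med, q3 = (np.percentile(s, [25, 50, 75]) if len(s)
                           else (np.nan,) * 3)
            rows.append({
                "variable": var, "level": f"median_iqr_{name}",
                "n_high": len(a) if name == "HIGH" else np.nan,
                "pct_high": np.nan, "n_low": len(b) if name == "LOW" else np.nan,
                "pct_low": np.nan,
                "p_chi_square": np.nan, "p_fisher": np.nan,
                "p_mann_whitney": p_mw if name == "HIGH" else np.nan,
                "median": med, "q1": q1, "q3": q3,
            })
    return pd.DataFrame(rows)
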