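"""Behavioural and hormonal statistics for the sex-stratified stress design.

The analysis plan mirrors the study: an Anderson-Darling normality gate,
a two-factor general linear model (treatment x sex, partial sums of
squares) with within-sex follow-ups when the interaction is significant,
Kaplan-Meier / log-rank comparisons for the censored tonic-immobility
latencies, an exact binomial test for the paired dominance contests, and a
pooled-variance t-test on log-transformed hormone titres.

Standard machinery (OLS/ANOVA, product-limit estimation, log-rank) is
delegated to statsmodels and lifelines; the thin result types keep every
reported statistic (name, value, df, P) in one traceable place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "AnovaTable",
    "anderson_darling",
    "two_way_glm",
    "within_sex_effect",
    "km_curve",
    "logrank",
    "dominance_binomial",
    "hormone_t_test",
]


@dataclass(frozen=True)
class TestResult:
    """One reported statistic: name, value, degrees of freedom, P."""

    statistic_name: str
    value: float
    df: float | tuple[float, float]
    p_value: float

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class AnovaTable:
    """F tests for a 2x2 treatment x sex model with interaction."""

    treatment: TestResult
    sex: TestResult
    interaction: TestResult
    residual_df: int
    degenerate: bool = False


def anderson_darling(values) -> TestResult:
    """Anderson-Darling test of composite normality (parameters estimated).

    Uses the small-sample corrected statistic
    ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)`` and the standard piecewise
    exponential P approximation for the estimated-parameters case.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    with warnings.catch_warnings():
        # scipy >= 1.17 warns about its own p-value methods; only the
        # statistic is used here, the P comes from the corrected formula
        warnings.simplefilter("ignore", FutureWarning)
        a2 = st.anderson(x, dist="norm").statistic
    n = x.size
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s >= 0.34:
        p = math.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s >= 0.2:
        p = 1.0 - math.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - math.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return TestResult("A2", float(a2s), float(n), float(min(max(p, 0.0), 1.0)))


def _check_cells(records: pd.DataFrame, response: str) -> None:
    for col in ("treatment", "sex", response):
        if col not in records.columns:
            raise ValueError(f"records table lacks required column {col!r}")
    counts = records.groupby(["treatment", "sex"], observed=True).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError(
            "empty treatment x sex cell: interaction is inestimable "
            f"(cell counts: {counts.to_dict()})"
        )


def two_way_glm(
    records: pd.DataFrame, response: str, ss_type: int = 3
) -> AnovaTable:
    """Two-factor GLM of ``response`` on treatment, sex and their interaction.

    Partial (Type III) sums of squares with sum-to-zero factor coding by
    default — the convention that reproduces the study's F values on its
    unbalanced design; ``ss_type=1`` gives sequential SS.  A constant
    response is flagged degenerate with all F = 0.
    """
    _check_cells(records, response)
    if ss_type not in (1, 3):
        raise ValueError("ss_type must be 1 or 3")
    df = records.rename(columns={response: "_y"})
    n = len(df)
    if np.ptp(df["_y"].to_numpy(dtype=float)) == 0:
        zero = lambda name: TestResult(name, 0.0, (1.0, float(n - 4)), 1.0)
        return AnovaTable(
            zero("F_treatment"), zero("F_sex"), zero("F_interaction"),
            residual_df=n - 4, degenerate=True,
        )
    model = smf.ols(
        "_y ~ C(treatment, Sum) * C(sex, Sum)", data=df
    ).fit()
    tbl = anova_lm(model, typ=ss_type)
    resid_df = int(tbl.loc["Residual", "df"])

    def row(label: str, name: str) -> TestResult:
        f = float(tbl.loc[label, "F"])
        p = float(tbl.loc[label, "PR(>F)"])
        return TestResult(name, f, (float(tbl.loc[label, "df"]), float(resid_df)), p)

    return AnovaTable(
        treatment=row("C(treatment, Sum)", "F_treatment"),
        sex=row("C(sex, Sum)", "F_sex"),
        interaction=row("C(treatment, Sum):C(sex, Sum)", "F_interaction"),
        residual_df=resid_df,
    )


def within_sex_effect(records: pd.DataFrame, response: str, sex: str) -> TestResult:
    """One-way F test of treatment within one sex stratum.

    Equivalent to the squared pooled-variance t; df (1, n-2) uses the
    stratum's own residual variance, matching the study's follow-up dfs.
    """
    sub = records[records["sex"] == sex]
    groups = [
        sub.loc[sub["treatment"] == t, response].to_numpy(dtype=float)
        for t in ("ES", "C")
    ]
    if any(len(g) == 0 for g in groups):
        raise ValueError(f"sex={sex!r} stratum lacks one of the treatment arms")
    f, p = st.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    if np.isnan(f):  # zero within-group variance
        f, p = 0.0, 1.0
    return TestResult("F_treatment", float(f), (1.0, float(n - 2)), float(p))


def km_curve(times, event_flags) -> pd.DataFrame:
    """Product-limit survival estimate.

    ``event_flags`` is 1/True for an observed event and 0/False for a
    right-censored time.  Returns a table (time, at_risk, events, censored,
    survival) with one row per distinct observed time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter().fit(t, event_observed=e)
    ev = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "events": ev["observed"].to_numpy(dtype=int),
            "censored": ev["censored"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
        }
    )
    return out[out["time"] > 0.0].reset_index(drop=True) if 0.0 not in t else out


def logrank(
    times_a, events_a, times_b, events_b
) -> TestResult:
    """Two-group log-rank test (chi-square, df = 1).

    Observed-minus-expected events accumulated over distinct event times
    with the hypergeometric variance (ties handled the standard way);
    symmetric in the two groups.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group: log-rank undefined")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult("X2", float(res.test_statistic), 1.0, float(res.p_value))


def dominance_binomial(
    pairs: pd.DataFrame, convention: str = "doubling"
) -> TestResult:
    """Exact binomial test of the ES win proportion against 1/2.

    Two-sided by doubling the smaller tail (capped at 1), the convention
    under which 1 ES win in 9 pairs gives P = 0.0391; the minimum-likelihood
    convention is available via ``convention="minlike"``.  All pairs must
    be of one sex — stratify before calling.
    """
    if len(pairs) == 0:
        raise ValueError("no dominance pairs supplied")
    if pairs["sex"].nunique() != 1:
        raise ValueError("mixed-sex pair table: stratify by sex first")
    bad = set(pairs["winner"]) - {"ES", "C"}
    if bad:
        raise ValueError(f"unknown winner labels: {sorted(bad)}")
    n = len(pairs)
    k = int((pairs["winner"] == "ES").sum())
    if convention == "doubling":
        lower = st.binom.cdf(k, n, 0.5)
        upper = st.binom.sf(k - 1, n, 0.5)
        p = min(1.0, 2.0 * min(lower, upper))
    elif convention == "minlike":
        p = st.binomtest(k, n, 0.5).pvalue
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return TestResult("ES_wins", float(k), float(n), float(p))


def hormone_t_test(
    group_es, group_c, log_transform: bool = True
) -> TestResult:
    """Pooled-variance two-sample t-test, optionally on log concentrations.

    df = n1 + n2 - 2 (the study's t_14 at n = 8 per arm implies the pooled
    rather than Welch form).  The t statistic is invariant to the log base.
    """
    a = np.asarray(group_es, dtype=float)
    b = np.asarray(group_c, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("nonpositive concentration: log-transform undefined")
        a, b = np.log(a), np.log(b)
    t, p = st.ttest_ind(a, b, equal_var=True)
    return TestResult("t", float(t), float(a.size + b.size - 2), float(p))
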