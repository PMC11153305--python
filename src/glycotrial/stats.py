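"""Trial statistics: contingency testing, FDR correction, mixed models.

Categorical endpoints are tested with Pearson's chi-squared; when the
chi-squared assumptions are violated (any expected cell count below 5) and
the table is 2x2, a two-sided Fisher's exact test is used instead. 2x2
chi-squared tests carry the Yates continuity correction. Continuous
endpoints are analysed with a linear mixed model on the follow-up visits:
fixed effects for time (categorical) and time-by-arm interaction, adjusted
for the baseline value of the outcome and the randomisation stratifiers
(sex, weight stratum), with a random intercept per participant; the
treatment effect at a timepoint is the time-by-arm contrast with a Wald 95%
CI. Secondary-outcome p-values are corrected with the Benjamini-Hochberg
step-up procedure. Missing data are handled complete-case per timepoint; no
imputation.

Fisher's exact test is computed by exact integer-combinatorics enumeration
of the conditional (hypergeometric) distribution, two-sided by summing the
probabilities of all tables no more probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

EXPECTED_COUNT_RULE = 5.0  # chi-squared assumption: all expected cells >= 5


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero row or column cannot be tested."""


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of an association test, with audit fields."""

    test_used: str  # chi_squared | chi_squared_yates | fisher_exact
    p_value: float
    statistic: float | None
    df: int | None
    expected_counts: np.ndarray
    min_expected: float


@dataclass(frozen=True)
class TreatmentEffect:
    """Adjusted treatment-effect estimate from the mixed model."""

    outcome: str
    timepoint: int
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    model_spec: str
    n_obs: int


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise DegenerateTableError("table has an all-zero row or column")
    return t.astype(int)


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence (row total x col total / n)."""
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Conditions on both margins and enumerates the hypergeometric
    distribution with exact integer arithmetic: the p-value is the sum of
    probabilities of all tables whose point probability does not exceed the
    observed one (point-probability ordering), so no floating-point tie
    tolerance is needed. Degenerate margins give p = 1 by convention.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    # unnormalised weights w_k = C(r1,k) C(r2,c1-k); P(k) = w_k / C(n,c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = sum(
        w_k
        for k in range(lo, hi + 1)
        if (w_k := math.comb(r1, k) * math.comb(r2, c1 - k)) <= w_obs
    )
    return float(Fraction(num, math.comb(n, c1)))


def association_test(table) -> ContingencyResult:
    """Test association between trial arm and an ordered categorical outcome.

    Pearson chi-squared (Yates-corrected iff 2x2); falls back to the
    two-sided Fisher exact test when the table is 2x2 and any expected cell
    count is below 5.
    """
    t = _validate_table(table)
    exp = expected_counts(t)
    min_exp = float(exp.min())
    is_2x2 = t.shape == (2, 2)
    if is_2x2 and min_exp < EXPECTED_COUNT_RULE:
        p = fisher_exact_2x2(t)
        return ContingencyResult(
            test_used="fisher_exact", p_value=p, statistic=None, df=None,
            expected_counts=exp, min_expected=min_exp,
        )
    chi2, p, df, _ = scipy.stats.chi2_contingency(t, correction=is_2x2)
    return ContingencyResult(
        test_used="chi_squared_yates" if is_2x2 else "chi_squared",
        p_value=float(p), statistic=float(chi2), df=int(df),
        expected_counts=exp, min_expected=min_exp,
    )


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(adjusted, reject)`` in the input order; adjusted p-values are
    the standard step-up minima capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def two_sample_t_test(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sided independent Student's t-test with pooled variance.

    Returns ``(statistic, p_value)``; both groups need n >= 2 and at least
    one group must have non-zero variance.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("t-test undefined: zero variance in both groups")
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def select_analysis_set(cohort: pd.DataFrame, analysis_set: str) -> pd.DataFrame:
    """Subset a long-format cohort for intention-to-treat or per-protocol analysis.

    ITT keeps every participant with a baseline visit. PP keeps intervention
    (FMD) participants who were compliant with the full programme and
    control participants who completed follow-up (a 12-month visit). No
    imputation is performed.
    """
    if analysis_set not in ("ITT", "PP"):
        raise ValueError("analysis_set must be 'ITT' or 'PP'")
    has_baseline = set(cohort.loc[cohort["timepoint_months"] == 0, "participant_id"])
    out = cohort[cohort["participant_id"].isin(has_baseline)]
    if analysis_set == "ITT":
        return out.copy()
    base = out[out["timepoint_months"] == 0]
    completers = set(out.loc[out["timepoint_months"] == 12, "participant_id"])
    keep = set()
    for _, r in base.iterrows():
        if r["arm"] == "FMD":
            if bool(r.get("compliant", False)) and r["participant_id"] in completers:
                keep.add(r["participant_id"])
        elif r["participant_id"] in completers:
            keep.add(r["participant_id"])
    return out[out["participant_id"].isin(keep)].copy()


class TreatmentEffectEstimator(BaseEstimator):
    """Linear mixed model for the adjusted treatment effect on one outcome.

    Follow-up observations (6 and 12 months) are modelled with fixed effects
    for time (categorical), time-by-arm interaction, the baseline outcome
    value, sex and weight stratum, and a per-participant random intercept,
    fit by REML. The fitted attributes expose the time-by-arm contrast at
    ``timepoint`` (Wald 95% CI), the trial's adjusted estimated treatment
    effect.

    Parameters
    ----------
    outcome : str
        Column of the long-format cohort to model.
    timepoint : int, default 12
        Follow-up month whose contrast is reported.
    adjust_for_weight : bool, default False
        Add a fixed effect for concurrent body weight (post-hoc model).
    """

    def __init__(self, outcome: str, timepoint: int = 12, adjust_for_weight: bool = False):
        self.outcome = outcome
        self.timepoint = timepoint
        self.adjust_for_weight = adjust_for_weight

    def fit(self, X: pd.DataFrame, y=None) -> "TreatmentEffectEstimator":
        df = _mixed_model_frame(X, self.outcome, self.adjust_for_weight)
        if df["time"].nunique() < 1 or self.timepoint not in set(df["time"]):
            raise ValueError(f"no follow-up data at {self.timepoint} months for {self.outcome!r}")
        formula = "value ~ C(time) + C(time):fmd + baseline + C(sex) + C(weight_stratum)"
        if self.adjust_for_weight:
            formula += " + weight_now"
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        with np.errstate(all="ignore"):
            result = model.fit(reml=True, method=["lbfgs", "cg"])
        if not np.all(np.isfinite(result.params)):
            raise RuntimeError(
                f"mixed model for {self.outcome!r} failed to converge: {result.summary()}"
            )
        term = f"C(time)[{self.timepoint}]:fmd"
        if term not in result.params.index:
            raise RuntimeError(f"contrast term {term!r} absent from fitted model")
        est = float(result.params[term])
        se = float(result.bse[term])
        z = scipy.stats.norm.ppf(0.975)
        self.result_ = result
        self.effect_ = TreatmentEffect(
            outcome=self.outcome,
            timepoint=self.timepoint,
            estimate=est,
            ci_low=est - z * se,
            ci_high=est + z * se,
            p_value=float(result.pvalues[term]),
            model_spec=formula + " + (1 | participant)",
            n_obs=int(len(df)),
        )
        return self

    def get_effect(self) -> TreatmentEffect:
        if not hasattr(self, "effect_"):
            raise RuntimeError("estimator not fitted")
        return self.effect_


def fit_treatment_effect(
    long_data: pd.DataFrame,
    outcome: str,
    timepoint: int = 12,
    adjust_for_weight: bool = False,
) -> TreatmentEffect:
    """Thin wrapper over :class:`TreatmentEffectEstimator`."""
    return (
        TreatmentEffectEstimator(outcome, timepoint=timepoint, adjust_for_weight=adjust_for_weight)
        .fit(long_data)
        .get_effect()
    )


def _mixed_model_frame(cohort: pd.DataFrame, outcome: str, with_weight: bool) -> pd.DataFrame:
    """Reshape long cohort data into the complete-case mixed-model frame."""
    required = {"participant_id", "arm", "timepoint_months", "sex", "weight_stratum", outcome}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks columns: {sorted(missing)}")
    timepoints = sorted(cohort["timepoint_months"].unique())
    if len(timepoints) < 2 or 0 not in timepoints:
        raise ValueError("need a baseline visit and at least one follow-up timepoint")
    base = (
        cohort[cohort["timepoint_months"] == 0]
        .set_index("participant_id")[outcome]
        .rename("baseline")
    )
    fu = cohort[cohort["timepoint_months"] > 0].copy()
    fu = fu.rename(columns={outcome: "value", "timepoint_months": "time"})
    cols = ["participant_id", "arm", "time", "value", "sex", "weight_stratum"]
    if with_weight:
        fu = fu.rename(columns={"weight_kg": "weight_now"})
        cols.append("weight_now")
    fu = fu[cols].join(base, on="participant_id")
    fu["fmd"] = (fu["arm"] == "FMD").astype(int)
    return fu.dropna(subset=["value", "baseline"]).reset_index(drop=True)
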