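"""Group-level statistics.

Trial-wise logistic regressions with a participant random intercept (with a
participant-clustered robust fallback), 2x2 between-subjects ANOVAs on
participant summaries, and pooled-variance two-sample comparisons with
Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "RegressionSpec",
    "build_formula",
    "glmm_trialwise",
    "anova_2x2",
    "two_sample_compare",
    "TwoSampleResult",
]


@dataclass(frozen=True)
class RegressionSpec:
    """Specification of a trial-wise logistic regression.

    ``outcome`` is ``"explore"`` or ``"correct"``; ``s_obs`` (trials since the
    last observed jump) is crossed with ``group`` (and ``condition`` when
    ``with_condition``), while ``ell`` (trials since the last explore) and its
    interactions enter as controls.  ``controls="minimal"`` includes only the
    ``ell`` main effect plus its interaction with group; ``"full"`` crosses
    ``ell`` with every grouping factor.
    """

    outcome: str = "explore"
    with_condition: bool = False
    controls: str = "minimal"

    def __post_init__(self) -> None:
        if self.outcome not in ("explore", "correct"):
            raise ValueError("outcome must be 'explore' or 'correct'")
        if self.controls not in ("minimal", "full", "none"):
            raise ValueError("controls must be 'minimal', 'full' or 'none'")


def build_formula(spec: RegressionSpec, single_group: bool = False) -> str:
    """Patsy formula for the fixed-effects part of the regression."""
    factors = [] if single_group else ["C(group)"]
    if spec.with_condition:
        factors.append("C(condition)")
    if factors:
        rhs = " * ".join(["s_obs"] + factors)
    else:
        rhs = "s_obs"
    if spec.controls == "minimal":
        rhs += " + ell"
        if not single_group:
            rhs += " + ell:C(group)"
    elif spec.controls == "full" and factors:
        rhs += " + " + " * ".join(["ell"] + factors)
    elif spec.controls == "full":
        rhs += " + ell"
    return f"{spec.outcome} ~ {rhs}"


def _prepare(trials: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    from .metrics import add_ell, label_explore, trials_since_observed_jump

    df = trials
    if "explore" not in df.columns:
        df = label_explore(df)
    if "ell" not in df.columns:
        df = add_ell(df)
    if "s_obs" not in df.columns:
        df = trials_since_observed_jump(df)
    # The s_obs column records the counter *after* each trial's observation
    # (it is 0 on the trial where a jump is seen).  As a predictor of the same
    # trial's choice it must be the value carried in from the previous trial,
    # so lag it within participant; the first trial starts at 0.
    df = df.copy()
    df["s_obs"] = (
        df.groupby("participant_id", sort=False)["s_obs"].shift(1).fillna(0)
    )
    df = df[df["explore"].notna() & df["ell"].notna()].copy()
    df["explore"] = df["explore"].astype(float)
    df["ell"] = df["ell"].astype(float)
    df["s_obs"] = df["s_obs"].astype(float)
    if spec.outcome == "correct" and "correct" not in df.columns:
        raise ValueError("outcome 'correct' requires a correct column")
    y = df[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} has no variation")
    return df


def _coef_table(terms, est, se) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": list(terms),
            "estimate": est,
            "std_error": se,
            "z": z,
            "p": p,
            "odds_ratio": np.exp(est),
        }
    )


def glmm_trialwise(
    trials: pd.DataFrame,
    spec: Optional[RegressionSpec] = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Trial-wise logistic regression with a participant random intercept.

    ``method="mixed"`` fits a variational Bayes random-intercept logistic
    model; ``"cluster"`` fits a plain logit with participant-clustered robust
    standard errors; ``"auto"`` tries the mixed fit and falls back to the
    clustered fit on failure.  Returns a coefficient table (term, estimate,
    std_error, z, p, odds_ratio) with ``.attrs["method"]`` recording which
    route produced it and ``.attrs["fallback"]`` whether the fallback fired.
    """
    if spec is None:
        spec = RegressionSpec()
    if method not in ("auto", "mixed", "cluster"):
        raise ValueError("method must be 'auto', 'mixed' or 'cluster'")
    df = _prepare(trials, spec)
    single_group = df["group"].nunique() < 2
    formula = build_formula(spec, single_group=single_group)

    fallback = False
    table = None
    if method in ("auto", "mixed"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.BinomialBayesMixedGLM.from_formula(
                    formula, {"participant": "0 + C(participant_id)"}, df
                )
                fit = model.fit_vb()
            k = len(fit.fe_mean)
            table = _coef_table(model.fep_names, fit.fe_mean, fit.fe_sd[:k])
            table.attrs["method"] = "mixed"
        except Exception:
            if method == "mixed":
                raise
            fallback = True
    if table is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.logit(formula, df).fit(
                disp=0,
                cov_type="cluster",
                cov_kwds={"groups": df["participant_id"]},
            )
        table = _coef_table(fit.params.index, fit.params.to_numpy(), fit.bse.to_numpy())
        table.attrs["method"] = "cluster"
    table.attrs["fallback"] = fallback
    table.attrs["formula"] = formula
    return table


def anova_2x2(
    summaries: pd.DataFrame,
    value: str,
    group_col: str = "group",
    cond_col: str = "condition",
) -> pd.DataFrame:
    """Between-subjects 2x2 ANOVA (group x condition) on participant summaries.

    One row per effect with sum-of-squares, F, numerator/denominator df and p
    (type-II sums of squares; cells need not be perfectly balanced).
    """
    cells = summaries.groupby([group_col, cond_col]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise ValueError("need observations in all four group x condition cells")
    model = smf.ols(
        f"{value} ~ C({group_col}) * C({cond_col})", data=summaries
    ).fit()
    tbl = sm.stats.anova_lm(model, typ=2)
    resid_df = float(tbl.loc["Residual", "df"])
    out = tbl.reset_index().rename(
        columns={"index": "effect", "sum_sq": "ss", "df": "df_num", "PR(>F)": "p"}
    )
    out["df_den"] = resid_df
    return out


@dataclass(frozen=True)
class TwoSampleResult:
    t: float
    df: float
    p: float
    cohen_d: float
    mean_a: float
    mean_b: float


def two_sample_compare(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> TwoSampleResult:
    """Two-sample t-test with Cohen's d (pooled SD).

    Defaults to the pooled-variance test (df = n1 + n2 - 2); ``equal_var=False``
    gives the Welch variant.  Cohen's d always uses the pooled SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and a.mean() == b.mean():
        return TwoSampleResult(0.0, float(len(a) + len(b) - 2), 1.0, 0.0,
                               float(a.mean()), float(b.mean()))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
    return TwoSampleResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        cohen_d=float(d),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
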