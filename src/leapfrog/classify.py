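"""Per-participant strategy classification by BIC.

Each participant's trial-level explore/exploit sequence is fit with two
models of the exploration hazard:

* an intercept-only model (constant explore probability — reflexive), and
* a logit-linear model in the lag since the last exploratory choice, with
  the slope constrained nonnegative (rising hazard — reflective).

The winner is the model with the lower BIC (= -2*loglik + k*ln(n), n the
count of labeled trials); ties break toward the simpler intercept model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .metrics import add_ell, label_explore

__all__ = [
    "HazardFit",
    "fit_intercept",
    "fit_linear",
    "classify_participant",
    "classify_cohort",
    "cohort_classification",
    "chi_square_from_counts",
]

_EPS = 1e-12


@dataclass(frozen=True)
class HazardFit:
    model: str  # "intercept" or "linear"
    intercept: float
    slope: Optional[float]
    loglik: float
    n: int
    k: int
    winner: bool = False

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)


def _bernoulli_loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _extract(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = trials
    if "explore" not in df.columns:
        df = label_explore(df)
    if "ell" not in df.columns:
        df = add_ell(df)
    sub = df[df["explore"].notna() & df["ell"].notna()]
    return sub["explore"].astype(float).to_numpy(), sub["ell"].astype(float).to_numpy()


def fit_intercept(trials: pd.DataFrame) -> HazardFit:
    """Constant-hazard Bernoulli MLE (k = 1).

    Degenerate participants (0 or 100% exploration) get a continuity
    correction of 0.5 successes/failures so the log-likelihood stays finite.
    """
    y, _ = _extract(trials)
    n = len(y)
    if n == 0:
        raise ValueError("no labeled trials")
    p = float(y.mean())
    if p in (0.0, 1.0):
        p = (y.sum() + 0.5) / (n + 1.0)
    ll = _bernoulli_loglik(y, np.full(n, p))
    return HazardFit(
        model="intercept", intercept=float(special.logit(p)), slope=None,
        loglik=ll, n=n, k=1,
    )


def fit_linear(trials: pd.DataFrame, variant: str = "logit") -> HazardFit:
    """Hazard rising linearly in the lag since the last explore (k = 2).

    ``variant="logit"`` (default) models the explore probability as
    logistic(intercept + slope*ell) with slope >= 0 at the trial level.
    ``variant="linear_prob"`` uses a clipped linear-probability link for
    sensitivity analysis.  When the nonnegativity constraint binds, the fit
    collapses to the intercept model's likelihood.
    """
    if variant not in ("logit", "linear_prob"):
        raise ValueError("variant must be 'logit' or 'linear_prob'")
    y, ell = _extract(trials)
    n = len(y)
    if n == 0:
        raise ValueError("no labeled trials")
    if len(np.unique(ell)) < 2:
        raise ValueError("need at least two distinct lags for the linear model")

    base = fit_intercept(trials)

    if variant == "logit":
        def nll(params):
            b0, b1 = params
            return -_bernoulli_loglik(y, special.expit(b0 + b1 * ell))
        x0 = (base.intercept, 0.01)
        bounds = [(-20.0, 20.0), (0.0, 10.0)]
    else:
        def nll(params):
            a, b = params
            return -_bernoulli_loglik(y, np.clip(a + b * ell, _EPS, 1.0 - _EPS))
        x0 = (float(y.mean()) or 0.01, 0.0)
        bounds = [(0.0, 1.0), (0.0, 1.0)]

    res = optimize.minimize(nll, x0=x0, bounds=bounds, method="L-BFGS-B")
    ll = -float(res.fun)
    b0, b1 = (float(v) for v in res.x)
    # The constrained optimum can never fall below the slope-0 solution; if the
    # optimizer stalls, fall back to the intercept MLE with slope pinned at 0.
    if ll < base.loglik:
        ll = base.loglik
        b0 = base.intercept if variant == "logit" else float(special.expit(base.intercept))
        b1 = 0.0
    return HazardFit(model="linear", intercept=b0, slope=b1, loglik=ll, n=n, k=2)


def classify_participant(
    trials: pd.DataFrame, variant: str = "logit"
) -> tuple[str, HazardFit, HazardFit]:
    """Return (winner, intercept_fit, linear_fit); ties favor the intercept."""
    fi = fit_intercept(trials)
    fl = fit_linear(trials, variant=variant)
    if fl.bic < fi.bic:
        winner = "reflective"
        fl = HazardFit(**{**fl.__dict__, "winner": True})
    else:
        winner = "reflexive"
        fi = HazardFit(**{**fi.__dict__, "winner": True})
    return winner, fi, fl


def classify_cohort(trials: pd.DataFrame, variant: str = "logit") -> pd.DataFrame:
    """Per-participant fit table over a multi-participant trial table."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        winner, fi, fl = classify_participant(sub, variant=variant)
        rows.append(
            {
                "participant_id": pid,
                "group": sub["group"].iloc[0],
                "condition": sub["condition"].iloc[0],
                "model": winner,
                "intercept": fl.intercept,
                "slope": fl.slope,
                "loglik_intercept": fi.loglik,
                "loglik_linear": fl.loglik,
                "n": fl.n,
                "bic_intercept": fi.bic,
                "bic_linear": fl.bic,
                "winner": winner,
            }
        )
    return pd.DataFrame(rows)


def cohort_classification(fits: pd.DataFrame) -> dict:
    """Counts of winners per group plus a 2x2 chi-square test with phi.

    ``fits`` is the frame from :func:`classify_cohort` (or any frame with
    ``group`` and ``winner`` columns).  The chi-square uses no continuity
    correction, matching conventional reporting for 2x2 strategy tables.
    """
    groups = list(pd.unique(fits["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    table = np.zeros((2, 2), dtype=int)
    counts = {}
    for i, g in enumerate(groups):
        sub = fits[fits["group"] == g]
        if sub.empty:
            raise ValueError(f"empty group {g!r}")
        n_linear = int((sub["winner"] == "reflective").sum())
        n_int = int((sub["winner"] == "reflexive").sum())
        table[i] = (n_linear, n_int)
        counts[g] = {"reflective": n_linear, "reflexive": n_int, "n": len(sub)}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n_total = int(table.sum())
    return {
        "counts": counts,
        "chi2": float(chi2),
        "p": float(p),
        "phi": float(np.sqrt(chi2 / n_total)),
        "n": n_total,
    }


def chi_square_from_counts(
    linear_a: int, n_a: int, linear_b: int, n_b: int
) -> dict:
    """Worked-example 2x2 chi-square from marginal winner counts."""
    table = np.array(
        [[linear_a, n_a - linear_a], [linear_b, n_b - linear_b]], dtype=int
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n = n_a + n_b
    return {"chi2": float(chi2), "p": float(p), "phi": float(np.sqrt(chi2 / n)), "n": n}
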