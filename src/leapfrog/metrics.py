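"""Trial-level behavioral metrics.

Derives explore/exploit labels, performance, exploration rates, exploration
hazard curves, and the covariates used by the regression analyses
(trials since last explore ``ell``, trials since last observed jump
``s_obs``) from a canonical trial table.

Labeling convention: a choice is *exploitive* when it picks the option with
the highest reward observed so far by that participant, *exploratory*
otherwise.  Trials before both options have been observed once carry an NA
label and are excluded downstream.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_trials",
    "write_trials",
    "validate_trials",
    "label_explore",
    "performance",
    "exploration_rate",
    "hazard_curve",
    "trials_since_observed_jump",
    "median_rt",
    "participant_summaries",
]

REQUIRED_COLUMNS = ("participant_id", "group", "condition", "trial", "choice", "reward")
OPTIONAL_COLUMNS = ("rt_ms",)

#: Hazard-curve lags with fewer at-risk trials than this are flagged low-support.
DEFAULT_SUPPORT_THRESHOLD = 5


class SchemaError(ValueError):
    """Trial table fails schema validation."""


def validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing required column(s): {missing}")
    bad_choice = df.index[~df["choice"].isin([0, 1])]
    if len(bad_choice):
        raise SchemaError(
            f"choice must be 0 or 1; first offending row index: {bad_choice[0]}"
        )
    for pid, sub in df.groupby("participant_id", sort=False):
        t = sub["trial"].to_numpy()
        if not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise SchemaError(f"non-contiguous trials for participant {pid!r}")


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV (NA encoded as empty fields)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    validate_trials(df)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")


def _apply_per_participant(df: pd.DataFrame, fn) -> pd.Series:
    """Apply ``fn(sub) -> Series`` per participant and align to df's index."""
    pieces = [fn(sub) for _, sub in df.groupby("participant_id", sort=False)]
    return pd.concat(pieces).reindex(df.index)


def label_explore(df: pd.DataFrame) -> pd.DataFrame:
    """Append an ``explore`` column (1 explore, 0 exploit, NA pre-warm-up).

    A trial is exploitive iff its choice equals the option with the maximum
    reward observed by that participant on *previous* trials.  Trials before
    both options have been observed (or while the running maxima tie) are NA.
    """
    validate_trials(df)

    def _label(sub: pd.DataFrame) -> pd.Series:
        seen = [-np.inf, -np.inf]
        out = np.full(len(sub), np.nan)
        for i, (c, r) in enumerate(zip(sub["choice"].to_numpy(), sub["reward"].to_numpy())):
            if np.isfinite(seen[0]) and np.isfinite(seen[1]) and seen[0] != seen[1]:
                best_seen = 0 if seen[0] > seen[1] else 1
                out[i] = 0.0 if c == best_seen else 1.0
            seen[c] = max(seen[c], r)
        return pd.Series(out, index=sub.index)

    out = df.copy()
    out["explore"] = _apply_per_participant(df, _label).astype("Float64")
    return out


def performance(df: pd.DataFrame, truth: Optional[pd.DataFrame] = None) -> float:
    """Proportion of trials choosing the truly higher option.

    Uses the ``correct`` column when present; otherwise ``truth`` must supply
    the per-trial value trajectory (columns ``trial``, ``v0``, ``v1``).
    Restricted to labeled (non-NA explore) trials when labels are present.
    """
    if "correct" in df.columns:
        correct = df["correct"].astype(float)
    else:
        if truth is None:
            raise ValueError("need a 'correct' column or a truth trajectory")
        merged = df.merge(truth[["trial", "v0", "v1"]], on="trial", validate="m:1")
        if len(merged) != len(df):
            raise ValueError("truth trajectory does not align with trials")
        best = (merged["v1"] > merged["v0"]).astype(int)
        correct = (merged["choice"].to_numpy() == best.to_numpy()).astype(float)
        correct = pd.Series(correct, index=df.index)
    if "explore" in df.columns:
        mask = df["explore"].notna()
        if mask.any():
            return float(correct[mask].mean())
    return float(correct.mean())


def exploration_rate(df: pd.DataFrame) -> float:
    """Mean of the explore label over non-NA trials."""
    if "explore" not in df.columns:
        raise ValueError("run label_explore first")
    labeled = df["explore"].dropna()
    if labeled.empty:
        raise ValueError("no labeled trials")
    return float(labeled.mean())


def _ell_for_participant(explore: np.ndarray, before_first: str) -> np.ndarray:
    """Lag since last explore for one participant's labeled-trial sequence.

    ``ell = k`` marks the k-th labeled trial after the most recent exploratory
    choice (the trial on which the next explore can land at lag k).  Before
    the first explore, lags count from the first labeled trial unless
    ``before_first == "drop"``.
    """
    ell = np.full(explore.shape, np.nan)
    lag = 1
    seen_explore = False
    for i, e in enumerate(explore):
        if np.isnan(e):
            continue
        if seen_explore or before_first == "count":
            ell[i] = lag
        if e == 1.0:
            lag = 1
            seen_explore = True
        else:
            lag += 1
    return ell


def add_ell(df: pd.DataFrame, before_first: str = "count") -> pd.DataFrame:
    """Append the ``ell`` column (trials since last exploratory choice)."""
    if before_first not in ("count", "drop"):
        raise ValueError("before_first must be 'count' or 'drop'")
    if "explore" not in df.columns:
        df = label_explore(df)
    out = df.copy()
    out["ell"] = _apply_per_participant(
        out,
        lambda s: pd.Series(_ell_for_participant(
            s["explore"].astype(float).to_numpy(), before_first), index=s.index),
    ).astype("Float64")
    return out


def hazard_curve(
    df: pd.DataFrame,
    support_threshold: int = DEFAULT_SUPPORT_THRESHOLD,
    before_first: str = "count",
) -> pd.DataFrame:
    """Exploration rate by lag since the previous exploratory choice.

    Returns one row per lag with ``n_at_risk``, ``n_explore``, ``rate`` and a
    ``low_support`` flag for lags with fewer than ``support_threshold``
    at-risk trials.
    """
    if "ell" not in df.columns:
        df = add_ell(df, before_first=before_first)
    sub = df[df["ell"].notna() & df["explore"].notna()]
    grp = sub.groupby(sub["ell"].astype(int))["explore"]
    curve = pd.DataFrame(
        {
            "lag": grp.size().index,
            "n_at_risk": grp.size().to_numpy(),
            "n_explore": grp.sum().astype(int).to_numpy(),
        }
    ).reset_index(drop=True)
    curve["rate"] = curve["n_explore"] / curve["n_at_risk"]
    curve["low_support"] = curve["n_at_risk"] < support_threshold
    return curve


def trials_since_observed_jump(df: pd.DataFrame, count: str = "trials") -> pd.DataFrame:
    """Append ``s_obs``: trials since the participant last observed a jump.

    A jump is observed on a trial whose reward exceeds the participant's
    previous observed maximum for the chosen option (first observations never
    count).  ``s_obs`` is 0 on observed-jump trials and increments otherwise.
    With ``count="explores"`` the counter advances only on exploratory trials
    instead of every trial (alternative reading; see hazard-curve caveats).
    """
    if count not in ("trials", "explores"):
        raise ValueError("count must be 'trials' or 'explores'")
    if count == "explores" and "explore" not in df.columns:
        df = label_explore(df)

    def _sobs(sub: pd.DataFrame) -> pd.Series:
        seen = [-np.inf, -np.inf]
        out = np.zeros(len(sub), dtype=float)
        counter = 0
        explore_col = (
            sub["explore"].astype(float).to_numpy()
            if count == "explores"
            else None
        )
        for i, (c, r) in enumerate(zip(sub["choice"].to_numpy(), sub["reward"].to_numpy())):
            if np.isfinite(seen[c]) and r < seen[c]:
                raise SchemaError(
                    f"decreasing reward for option {c} (participant "
                    f"{sub['participant_id'].iloc[0]!r}, trial {sub['trial'].iloc[i]})"
                )
            jump_seen = np.isfinite(seen[c]) and r > seen[c]
            if jump_seen:
                counter = 0
            elif count == "trials":
                counter += 1
            elif explore_col[i] == 1.0:
                counter += 1
            out[i] = counter
            seen[c] = max(seen[c], r)
        return pd.Series(out, index=sub.index)

    out = df.copy()
    out["s_obs"] = _apply_per_participant(out, _sobs).astype("Float64")
    return out


def median_rt(df: pd.DataFrame) -> pd.Series:
    """Per-participant median reaction time in milliseconds (NaN-propagating)."""
    if "rt_ms" not in df.columns:
        raise ValueError("trial table has no rt_ms column")
    return df.groupby("participant_id", sort=False)["rt_ms"].median()


def participant_summaries(df: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: group, condition, performance, exploration, RT."""
    if "explore" not in df.columns:
        df = label_explore(df)
    rows = []
    for pid, sub in df.groupby("participant_id", sort=False):
        row = {
            "participant_id": pid,
            "group": sub["group"].iloc[0],
            "condition": sub["condition"].iloc[0],
            "n_trials": len(sub),
            "exploration_rate": exploration_rate(sub),
        }
        row["performance"] = performance(sub) if "correct" in sub.columns else np.nan
        row["median_rt_ms"] = (
            float(sub["rt_ms"].median()) if sub["rt_ms"].notna().any() else np.nan
        ) if "rt_ms" in sub.columns else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
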