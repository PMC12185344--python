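"""Mood instability and mood-behaviour coupling analyses.

Daily mood enters the pipeline three ways:

* instability — the within-participant standard deviation of daily PANAS
  scores, compared across the bipolar-disorder gradient;
* happiness coupling — the change in the happiness VAS over a session
  regressed on the session's summed (standardized) gamble outcome, with a
  gradient interaction;
* choice noisiness — session-wise inverse temperature (log beta) regressed
  on same-day positive mood (within-participant standardized) and, across
  participants, on mood instability itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .inference import PosteriorSummary, add_gradient_design, LocationScaleRegression

__all__ = [
    "mood_instability",
    "mood_instability_gradient",
    "happiness_outcome_regression",
    "mood_noisiness_coupling",
]


def mood_instability(mood: pd.DataFrame, min_days: int = 3) -> pd.DataFrame:
    """Per-participant SD of daily PANAS scores.

    Participants with fewer than ``min_days`` days are flagged
    ``valid=False`` (SDs NaN).  The SD is the sample standard deviation
    (ddof=1), invariant to adding a constant to a participant's series.
    """
    rows = []
    for pid, sub in mood.groupby("participant_id", sort=True):
        if sub["day"].duplicated().any():
            raise ValueError(f"duplicate days for participant {pid}")
        n = len(sub)
        ok = n >= min_days
        rows.append(
            {
                "participant_id": pid,
                "group": sub["group"].iloc[0],
                "sd_panas_pos": float(sub["panas_pos"].std(ddof=1)) if ok else np.nan,
                "sd_panas_neg": float(sub["panas_neg"].std(ddof=1)) if ok else np.nan,
                "mean_panas_pos": float(sub["panas_pos"].mean()),
                "n_days": n,
                "valid": ok,
            }
        )
    return pd.DataFrame(rows)


def _participant_regression(
    df: pd.DataFrame, value_col: str, extra_cols: tuple[str, ...] = ()
) -> PosteriorSummary:
    """Non-hierarchical Bayesian regression on one row per participant."""
    df, grad_cols = add_gradient_design(df, day_col=None)
    model = LocationScaleRegression(
        mean_cols=tuple(grad_cols) + ("age_z", "gender_c") + extra_cols,
        random_intercept=False,
        dispersion=False,
    )
    model.fit(df, df[value_col].to_numpy(float))
    return model.summary_


def mood_instability_gradient(
    mood: pd.DataFrame, participants: pd.DataFrame, scale: str = "pos", min_days: int = 3
) -> PosteriorSummary:
    """Gradient comparison of mood instability (one SD per participant).

    ``scale`` selects positive or negative PANAS.  Invalid participants
    (too few days) are dropped.
    """
    inst = mood_instability(mood, min_days=min_days)
    col = f"sd_panas_{scale}"
    df = inst[inst["valid"]].merge(
        participants[["participant_id", "age", "gender"]], on="participant_id"
    )
    if df.empty:
        raise ValueError("no participants with enough mood data")
    return _participant_regression(df, col)


def session_net_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Summed signed points per participant x day, with a cohort z-score."""
    net = (
        trials.groupby(["participant_id", "day"], sort=True)["outcome"]
        .sum()
        .rename("net_outcome")
        .reset_index()
    )
    sd = net["net_outcome"].std(ddof=0)
    if sd == 0:
        net["net_z"] = np.nan
    else:
        net["net_z"] = (net["net_outcome"] - net["net_outcome"].mean()) / sd
    return net


def happiness_outcome_regression(
    mood: pd.DataFrame, trials: pd.DataFrame, participants: pd.DataFrame
) -> PosteriorSummary:
    """Regression of the session happiness change on the session outcome.

    Outcome variable: post minus pre happiness VAS.  Predictors: the
    standardized session net outcome (``net_z``, the reported coupling),
    gradient codes, their interaction with ``net_z``
    (``net_z:grad_linear``), age and gender; random intercepts per
    participant.  Degenerate designs (all net outcomes equal) raise.
    """
    df = mood.dropna(subset=["vas_pre", "vas_post"]).copy()
    if df.empty:
        raise ValueError("no sessions with both pre and post VAS")
    net = session_net_outcomes(trials)
    if net["net_z"].isna().all():
        raise ValueError(
            "session net outcomes are constant; outcome coupling unidentifiable"
        )
    df = df.merge(net, on=["participant_id", "day"], how="inner")
    df = df.merge(participants[["participant_id", "age", "gender"]], on="participant_id")
    df["dvas"] = df["vas_post"] - df["vas_pre"]
    df, grad_cols = add_gradient_design(df, day_col=None)
    df["net_z:grad_linear"] = df["net_z"] * df["grad_linear"]
    model = LocationScaleRegression(
        mean_cols=("net_z",) + tuple(grad_cols) + ("net_z:grad_linear", "age_z", "gender_c"),
        random_intercept=True,
        dispersion=False,
    )
    model.fit(df, df["dvas"].to_numpy(float))
    return model.summary_


def mood_noisiness_coupling(
    mood: pd.DataFrame,
    fits: pd.DataFrame,
    participants: pd.DataFrame,
    min_days: int = 2,
) -> dict[str, PosteriorSummary]:
    """Mood and choice noisiness (inverse temperature), two readouts.

    ``daily``: session log beta on same-day positive PANAS
    (within-participant z-score) with a gradient interaction
    (``panas_z:grad_linear``) and random intercepts — does a participant
    choose more consistently on good-mood days, and more so along the
    gradient?  ``instability``: participant-mean log beta on the
    mood-instability SD across participants — do unstable-mood
    participants choose more noisily overall?  Participants with fewer
    than ``min_days`` mood days are excluded (with a warning) from the
    daily analysis.
    """
    df = fits.merge(
        mood[["participant_id", "day", "panas_pos"]], on=["participant_id", "day"]
    )
    df = df.merge(participants[["participant_id", "age", "gender"]], on="participant_id")
    counts = df.groupby("participant_id")["day"].transform("nunique")
    if (counts < min_days).any():
        dropped = df.loc[counts < min_days, "participant_id"].nunique()
        warnings.warn(
            f"excluding {dropped} participant(s) with fewer than {min_days} mood days",
            RuntimeWarning,
        )
        df = df[counts >= min_days]
    if df.empty:
        raise ValueError("no participants with enough paired mood/fit days")
    grp = df.groupby("participant_id")["panas_pos"]
    mu, sd = grp.transform("mean"), grp.transform("std").replace(0, np.nan)
    df["panas_z"] = ((df["panas_pos"] - mu) / sd).fillna(0.0)
    df, grad_cols = add_gradient_design(df, day_col="day")
    df["panas_z:grad_linear"] = df["panas_z"] * df["grad_linear"]
    model = LocationScaleRegression(
        mean_cols=("day_c", "panas_z") + tuple(grad_cols)
        + ("panas_z:grad_linear", "age_z", "gender_c"),
        random_intercept=True,
        random_slope_col="day_c",
        dispersion=False,
    )
    model.fit(df, df["log_beta_mean"].to_numpy(float))
    daily = model.summary_

    inst = mood_instability(mood)
    pm = (
        fits.groupby("participant_id", sort=True)
        .agg(mean_log_beta=("log_beta_mean", "mean"), group=("group", "first"))
        .reset_index()
    )
    pdf = pm.merge(inst[inst["valid"]], on=["participant_id", "group"]).merge(
        participants[["participant_id", "age", "gender"]], on="participant_id"
    )
    pdf["instability_z"] = (
        pdf["sd_panas_pos"] - pdf["sd_panas_pos"].mean()
    ) / max(pdf["sd_panas_pos"].std(), 1e-8)
    instability = _participant_regression(
        pdf, "mean_log_beta", extra_cols=("instability_z",)
    )
    return {"daily": daily, "instability": instability}
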