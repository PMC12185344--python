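"""Model-free behavioural statistics for the gamble task.

Three analyses that summarise choices without fitting the decision model:

* choice curves over bins of the displayed relative utility (reward
  utility minus loss utility, left minus right) — a task-performance
  check: the higher the left option's relative utility, the more often it
  should be chosen;
* dimension sensitivity — separate choice curves and logistic slopes for
  the win and the loss utility dimensions, whose asymmetry mirrors loss
  sensitivity;
* the outcome-history contrast — on trials where the two options' loss
  utilities differ most, the probability of picking the lower-loss option
  after a previous win minus after a previous loss, a model-free readout
  of history-dependent risk adaptation.

Displayed utilities use the on-screen convention (loss weight 1, no
history term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import LOGIT_CLIP
from scipy.special import expit

__all__ = [
    "BinnedChoiceCurve",
    "bin_choice_curve",
    "dimension_sensitivity",
    "outcome_history_contrast",
    "predictive_accuracy",
]


@dataclass
class BinnedChoiceCurve:
    """Per-bin counts and fraction of left choices over a utility difference."""

    bin_edges: np.ndarray
    counts: np.ndarray
    frac_left: np.ndarray
    dimension: str = "total"

    def __post_init__(self) -> None:
        ok = self.frac_left[~np.isnan(self.frac_left)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
                "frac_left": self.frac_left,
                "dimension": self.dimension,
            }
        )


def displayed_utilities(trials: pd.DataFrame) -> pd.DataFrame:
    """Add displayed-utility columns (loss weight 1, no history term).

    ``d_win`` and ``d_loss`` are the left-minus-right differences in
    reward utility (p*mag_win) and loss utility ((1-p)*mag_loss);
    ``d_total = d_win - d_loss`` is the relative utility shown on screen.
    """
    out = trials.copy()
    out["d_win"] = (
        out["p_win_left"] * out["mag_win_left"]
        - out["p_win_right"] * out["mag_win_right"]
    )
    out["d_loss"] = (1 - out["p_win_left"]) * out["mag_loss_left"] - (
        1 - out["p_win_right"]
    ) * out["mag_loss_right"]
    out["d_total"] = out["d_win"] - out["d_loss"]
    out["chose_left"] = (out["choice"] == "L").astype(float)
    return out


def _quantile_curve(x: np.ndarray, chose_left: np.ndarray, n_bins: int, dim: str):
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        raise ValueError("too few distinct utility values to form bins")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    sums = np.bincount(idx, weights=chose_left, minlength=edges.size - 1)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedChoiceCurve(edges, counts, frac, dimension=dim)


def bin_choice_curve(trials: pd.DataFrame, n_bins: int = 7) -> BinnedChoiceCurve:
    """Fraction of left choices per equal-count bin of relative utility."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    df = displayed_utilities(trials)
    return _quantile_curve(
        df["d_total"].to_numpy(), df["chose_left"].to_numpy(), n_bins, "total"
    )


def _logistic_slopes(df: pd.DataFrame) -> tuple[float, float]:
    """Per-dimension logistic slopes from chose_left ~ d_win + d_loss.

    Returns (win_slope, loss_slope), both oriented so that a positive
    slope means stronger sensitivity to that dimension; NaN when the fit
    is degenerate (e.g. perfect separation).
    """
    X = sm.add_constant(df[["d_win", "d_loss"]].to_numpy())
    y = df["chose_left"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
            return np.nan, np.nan
        return float(res.params[1]), float(-res.params[2])
    except Exception:
        return np.nan, np.nan


def dimension_sensitivity(
    trials: pd.DataFrame, n_bins: int = 7
) -> tuple[dict[str, BinnedChoiceCurve], pd.DataFrame]:
    """Win- vs loss-dimension choice curves and per-participant slopes.

    Returns ``(curves, slopes)``: pooled choice curves over the win and
    loss utility differences, and a per-participant table with logistic
    slopes for each dimension and their difference (win minus loss) — the
    model-free analogue of loss sensitivity.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    df = displayed_utilities(trials)
    curves = {
        "win": _quantile_curve(df["d_win"].to_numpy(), df["chose_left"].to_numpy(), n_bins, "win"),
        "loss": _quantile_curve(df["d_loss"].to_numpy(), df["chose_left"].to_numpy(), n_bins, "loss"),
    }
    rows = []
    for pid, sub in df.groupby("participant_id", sort=True):
        win_slope, loss_slope = _logistic_slopes(sub)
        rows.append(
            {
                "participant_id": pid,
                "win_slope": win_slope,
                "loss_slope": loss_slope,
                "slope_diff": win_slope - loss_slope,
                "n_trials": len(sub),
            }
        )
    return curves, pd.DataFrame(rows)


def outcome_history_contrast(
    trials: pd.DataFrame, extreme_fraction: float = 0.25
) -> pd.DataFrame:
    """Per-participant outcome-history contrast on extreme loss-utility trials.

    Restricts to non-first trials in the top ``extreme_fraction`` of
    |loss-utility difference| (dataset-wide quantile), labels the option
    with the lower loss utility (ties excluded), and computes

        P(choose lower-loss | previous win) - P(choose lower-loss | previous loss).

    Participants with an empty conditional cell are flagged
    ``valid=False`` with a NaN contrast.
    """
    if not 0 < extreme_fraction <= 1:
        raise ValueError("extreme_fraction must be in (0, 1]")
    df = displayed_utilities(trials)
    df = df.sort_values(["participant_id", "day", "trial"])
    prev_outcome = df.groupby(["participant_id", "day"], sort=False)["outcome"].shift(1)
    df["prev_sign"] = np.sign(prev_outcome)
    df = df[df["prev_sign"].notna() & (df["prev_sign"] != 0)]

    cut = np.quantile(np.abs(df["d_loss"]), 1 - extreme_fraction)
    df = df[np.abs(df["d_loss"]) >= cut]
    df = df[df["d_loss"] != 0]  # lower-loss label undefined on ties
    lower_left = df["d_loss"] < 0
    df = df.assign(chose_lower=np.where(lower_left, df["chose_left"], 1 - df["chose_left"]))

    rows = []
    for pid, sub in df.groupby("participant_id", sort=True):
        after_win = sub.loc[sub["prev_sign"] > 0, "chose_lower"]
        after_loss = sub.loc[sub["prev_sign"] < 0, "chose_lower"]
        valid = len(after_win) > 0 and len(after_loss) > 0
        rows.append(
            {
                "participant_id": pid,
                "contrast": float(after_win.mean() - after_loss.mean()) if valid else np.nan,
                "n_after_win": len(after_win),
                "n_after_loss": len(after_loss),
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)


def predictive_accuracy(
    trials: pd.DataFrame, fits: pd.DataFrame, by_group: bool = False
):
    """Fraction of trials whose modal model prediction matches the choice.

    ``fits`` holds one row per participant x day with posterior-mean
    parameters (``lam_mean``, ``gamma_mean``, ``log_beta_mean``).  Trials
    whose session lacks a fit are skipped with a warning.  Ties
    (predicted probability exactly 0.5) count as half correct.
    """
    df = displayed_utilities(trials).sort_values(["participant_id", "day", "trial"])
    prev_outcome = df.groupby(["participant_id", "day"], sort=False)["outcome"].shift(1)
    df["prev_sign"] = np.sign(prev_outcome).fillna(0.0)
    key_cols = ["participant_id", "day"]
    merged = df.merge(
        fits[key_cols + ["lam_mean", "gamma_mean", "log_beta_mean"]],
        on=key_cols,
        how="left",
    )
    missing = merged["lam_mean"].isna()
    if missing.any():
        n_miss = merged.loc[missing, key_cols].drop_duplicates().shape[0]
        warnings.warn(f"skipping {n_miss} session(s) without fits", RuntimeWarning)
        merged = merged[~missing]
    lam = merged["lam_mean"].to_numpy()
    gam = merged["gamma_mean"].to_numpy()
    beta = np.exp(merged["log_beta_mean"].to_numpy())
    du = merged["d_win"].to_numpy() - (lam + gam * merged["prev_sign"].to_numpy()) * (
        merged["d_loss"].to_numpy()
    )
    p_left = expit(np.clip(beta * du, -LOGIT_CLIP, LOGIT_CLIP))
    tie = p_left == 0.5
    correct = (p_left > 0.5) == (merged["chose_left"].to_numpy() > 0.5)
    score = np.where(tie, 0.5, correct.astype(float))
    merged = merged.assign(score=score)
    if by_group:
        return merged.groupby("group")["score"].mean()
    return float(score.mean())
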