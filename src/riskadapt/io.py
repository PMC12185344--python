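"""CSV dialects for the pipeline's tables.

All artifacts are UTF-8 CSV with a header row and fixed column sets:
trials and mood tables as produced by the generator (or exported from a
study), session-fits and coefficient-summary tables as produced by the
fitting and inference stages.  Choices are coded {L, R}; probabilities
are decimals.  Reading validates the schema (naming the offending
column), the choice coding, and the outcome/magnitude consistency of each
trial row, so that a malformed export fails loudly before analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIALS_COLUMNS",
    "MOOD_COLUMNS",
    "read_trials",
    "write_trials",
    "read_mood",
    "write_mood",
    "read_table",
    "write_table",
]

TRIALS_COLUMNS = [
    "participant_id", "group", "arm", "phase", "day", "trial",
    "p_win_left", "mag_win_left", "mag_loss_left",
    "p_win_right", "mag_win_right", "mag_loss_right",
    "choice", "outcome",
]

MOOD_COLUMNS = [
    "participant_id", "group", "day",
    "panas_pos", "panas_neg", "vas_pre", "vas_post",
]


class SchemaError(ValueError):
    """A table does not match its declared column set or coding."""


def _check_columns(df: pd.DataFrame, expected: list[str], name: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing:
        raise SchemaError(f"{name} table missing column(s): {missing}")
    if extra:
        raise SchemaError(f"{name} table has unexpected column(s): {extra}")


def validate_trials(df: pd.DataFrame) -> None:
    """Schema, coding and outcome-consistency checks for a trials table."""
    _check_columns(df, TRIALS_COLUMNS, "trials")
    bad = set(df["choice"].unique()) - {"L", "R"}
    if bad:
        raise SchemaError(f"choice must be coded L/R, found {sorted(map(str, bad))}")
    for side in ("left", "right"):
        p = df[f"p_win_{side}"]
        if ((p < 0) | (p > 1)).any():
            raise SchemaError(f"p_win_{side} outside [0, 1]")
    chosen_win = np.where(df["choice"] == "L", df["mag_win_left"], df["mag_win_right"])
    chosen_loss = np.where(df["choice"] == "L", df["mag_loss_left"], df["mag_loss_right"])
    ok = (df["outcome"] == chosen_win) | (df["outcome"] == -chosen_loss)
    if not ok.all():
        i = int(np.flatnonzero(~ok.to_numpy())[0])
        raise SchemaError(
            f"trial row {i}: outcome {df['outcome'].iloc[i]} inconsistent with the "
            "chosen option's magnitudes (previous-outcome chain would be corrupt)"
        )


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trials(df)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    validate_trials(df)
    df.to_csv(path, index=False, columns=TRIALS_COLUMNS)


def read_mood(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, MOOD_COLUMNS, "mood")
    return df


def write_mood(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, MOOD_COLUMNS, "mood")
    df.to_csv(path, index=False, columns=MOOD_COLUMNS)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a free-schema artifact table (fits, summaries, truth)."""
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
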