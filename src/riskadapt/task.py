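"""Core decision model for the wheel-of-fortune gamble task.

Each trial presents two gambles ("wheels"), each defined by a win
probability and win/loss point magnitudes.  An agent values an option by
its reward utility minus a weighted loss utility,

    U = p_win * mag_win - (lambda + gamma * prev) * (1 - p_win) * mag_loss,

where ``lambda`` is loss sensitivity, ``gamma`` modulates the loss weight
by the previous trial's outcome (``prev`` coded +1 after a win, -1 after a
loss, 0 on the first trial of a session), and chooses via a softmax with
inverse temperature ``beta``:

    p(choose left) = 1 / (1 + exp(beta * (U_right - U_left))).

Utilities are in raw points, so ``beta`` has units of 1/points.  This
module is pure computation: option utilities, the softmax choice rule,
trial simulation, and the session log-likelihood that all fitting builds
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "GambleOption",
    "ModelParams",
    "TrialRecord",
    "SessionData",
    "option_utility",
    "choice_prob_left",
    "simulate_trial",
    "session_log_likelihood",
]

# |beta * delta-utility| is clipped here before exponentiation; desk-scale
# inputs (points <= 200, beta ~ 0.1) never get near it.
LOGIT_CLIP = 500.0
# probability floor inside the log-likelihood
PROB_FLOOR = 1e-12
LOG_PROB_FLOOR = float(np.log(PROB_FLOOR))


@dataclass(frozen=True)
class GambleOption:
    """One wheel: win probability and win/loss magnitudes in points."""

    win_prob: float
    win_mag: float
    loss_mag: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.win_prob <= 1.0:
            raise ValueError(f"win_prob must be in [0, 1], got {self.win_prob}")
        if self.win_mag <= 0:
            raise ValueError(f"win_mag must be positive, got {self.win_mag}")
        if self.loss_mag <= 0:
            raise ValueError(f"loss_mag must be positive, got {self.loss_mag}")

    @property
    def expected_value(self) -> float:
        """p_win * mag_win - (1 - p_win) * mag_loss, in points."""
        return self.win_prob * self.win_mag - (1.0 - self.win_prob) * self.loss_mag


@dataclass(frozen=True)
class ModelParams:
    """Agent parameters: loss sensitivity, outcome-history weight, inverse temperature.

    ``loss_sensitivity`` (lambda) and ``outcome_history`` (gamma) are
    unbounded reals; the effective loss weight lambda + gamma*prev may go
    negative (risk seeking), which the model permits.
    ``inverse_temperature`` (beta, 1/points) must be non-negative.
    """

    loss_sensitivity: float
    outcome_history: float
    inverse_temperature: float

    def __post_init__(self) -> None:
        if self.inverse_temperature < 0:
            raise ValueError(
                f"inverse_temperature must be >= 0, got {self.inverse_temperature}"
            )


@dataclass
class TrialRecord:
    """One presented pair with the agent's history, choice, and outcome."""

    left: GambleOption
    right: GambleOption
    prev_outcome_sign: int
    choice_side: str  # 'L' or 'R'
    realized_outcome: float
    trial_index: int

    def __post_init__(self) -> None:
        if self.prev_outcome_sign not in (-1, 0, 1):
            raise ValueError("prev_outcome_sign must be -1, 0 or +1")
        if self.choice_side not in ("L", "R"):
            raise ValueError("choice_side must be 'L' or 'R'")
        chosen = self.left if self.choice_side == "L" else self.right
        if self.realized_outcome not in (chosen.win_mag, -chosen.loss_mag):
            raise ValueError(
                "realized_outcome must equal +win_mag or -loss_mag of the chosen option"
            )

    @property
    def chosen(self) -> GambleOption:
        return self.left if self.choice_side == "L" else self.right


@dataclass
class SessionData:
    """An ordered block of trials played by one participant on one day."""

    participant_id: str
    group: str
    day_index: int
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def validate_history_chain(self) -> None:
        """Check stored prev_outcome_sign against the realized outcome sequence."""
        for t, trial in enumerate(self.trials):
            expected = 0 if t == 0 else int(np.sign(self.trials[t - 1].realized_outcome))
            if trial.prev_outcome_sign != expected:
                raise ValueError(
                    f"trial {t}: prev_outcome_sign={trial.prev_outcome_sign} "
                    f"inconsistent with previous outcome (expected {expected})"
                )

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Columnar view used by the vectorised likelihood and fitters."""
        n = len(self.trials)
        out = {
            "p_left": np.empty(n),
            "wmag_left": np.empty(n),
            "lmag_left": np.empty(n),
            "p_right": np.empty(n),
            "wmag_right": np.empty(n),
            "lmag_right": np.empty(n),
            "prev_sign": np.empty(n),
            "chose_left": np.empty(n, dtype=bool),
            "outcome": np.empty(n),
        }
        for i, tr in enumerate(self.trials):
            out["p_left"][i] = tr.left.win_prob
            out["wmag_left"][i] = tr.left.win_mag
            out["lmag_left"][i] = tr.left.loss_mag
            out["p_right"][i] = tr.right.win_prob
            out["wmag_right"][i] = tr.right.win_mag
            out["lmag_right"][i] = tr.right.loss_mag
            out["prev_sign"][i] = tr.prev_outcome_sign
            out["chose_left"][i] = tr.choice_side == "L"
            out["outcome"][i] = tr.realized_outcome
        return out


def utilities_from_arrays(p, wmag, lmag, lam, gamma, prev_sign):
    """Vectorised option utility; all arguments broadcast."""
    return p * wmag - (lam + gamma * prev_sign) * (1.0 - p) * lmag


def option_utility(option: GambleOption, params: ModelParams, prev_sign: int) -> float:
    """Utility of one option given the previous trial's outcome sign."""
    if prev_sign not in (-1, 0, 1):
        raise ValueError(f"prev_sign must be -1, 0 or +1, got {prev_sign}")
    return float(
        utilities_from_arrays(
            option.win_prob,
            option.win_mag,
            option.loss_mag,
            params.loss_sensitivity,
            params.outcome_history,
            prev_sign,
        )
    )


def choice_prob_left(u_left, u_right, beta):
    """Softmax probability of choosing the left option.

    Overflow-safe: the logit beta*(u_left - u_right) is clipped at
    +/-``LOGIT_CLIP`` before the logistic transform.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta (inverse temperature) must be >= 0")
    x = np.clip(beta * (np.asarray(u_left, float) - np.asarray(u_right, float)),
                -LOGIT_CLIP, LOGIT_CLIP)
    p = expit(x)
    if p.ndim == 0:
        return float(p)
    return p


def simulate_trial(
    left: GambleOption,
    right: GambleOption,
    params: ModelParams,
    prev_sign: int,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Simulate one choice and its wheel outcome.

    The choice is drawn from the softmax; the wheel then lands on win with
    the chosen option's win probability, else loss.  Returns
    ``(choice_side, realized_outcome)``.
    """
    u_l = option_utility(left, params, prev_sign)
    u_r = option_utility(right, params, prev_sign)
    p_left = choice_prob_left(u_l, u_r, params.inverse_temperature)
    side = "L" if rng.random() < p_left else "R"
    chosen = left if side == "L" else right
    won = rng.random() < chosen.win_prob
    outcome = chosen.win_mag if won else -chosen.loss_mag
    return side, outcome


def _recompute_prev_sign(outcome: np.ndarray) -> np.ndarray:
    prev = np.zeros_like(outcome)
    prev[1:] = np.sign(outcome[:-1])
    return prev


def log_likelihood_arrays(arrs: dict[str, np.ndarray], lam, gamma, beta) -> float:
    """Session log-likelihood on the columnar trial representation.

    prev_sign is taken from ``arrs['prev_sign']`` (already validated or
    recomputed by the caller).  Per-trial probabilities are floored at
    ``PROB_FLOOR`` before the log.
    """
    u_l = utilities_from_arrays(
        arrs["p_left"], arrs["wmag_left"], arrs["lmag_left"], lam, gamma, arrs["prev_sign"]
    )
    u_r = utilities_from_arrays(
        arrs["p_right"], arrs["wmag_right"], arrs["lmag_right"], lam, gamma, arrs["prev_sign"]
    )
    x = np.clip(beta * (u_l - u_r), -LOGIT_CLIP, LOGIT_CLIP)
    sign = np.where(arrs["chose_left"], 1.0, -1.0)
    ll = log_expit(sign * x)
    return float(np.sum(np.maximum(ll, LOG_PROB_FLOOR)))


def session_log_likelihood(session: SessionData, params: ModelParams) -> float:
    """Log-likelihood of a session's observed choices under ``params``.

    The previous-outcome sign chain is recomputed from the session's own
    realized outcomes; a mismatch with the stored signs is a data-integrity
    error.  Always <= 0.
    """
    if len(session) == 0:
        raise ValueError("session has no trials")
    session.validate_history_chain()
    arrs = session.to_arrays()
    arrs["prev_sign"] = _recompute_prev_sign(arrs["outcome"])
    return log_likelihood_arrays(
        arrs,
        params.loss_sensitivity,
        params.outcome_history,
        params.inverse_temperature,
    )
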