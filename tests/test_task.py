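"""Core decision model: utilities, softmax rule, simulation, likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskadapt.task import (
    GambleOption,
    ModelParams,
    SessionData,
    TrialRecord,
    choice_prob_left,
    option_utility,
    session_log_likelihood,
    simulate_trial,
)
from riskadapt.synth import generate_session


OPT = GambleOption(win_prob=0.7, win_mag=100, loss_mag=50)


@pytest.mark.parametrize(
    "option, params, prev, expected",
    [
        # gamma = 0 reduces to plain expected utility
        (OPT, ModelParams(1.0, 0.0, 0.1), -1, 55.0),
        # history term raises the loss weight after a win
        (OPT, ModelParams(1.0, 0.2, 0.1), +1, 52.0),
        # sure win: loss term vanishes
        (GambleOption(1.0, 120, 30), ModelParams(2.0, 0.7, 0.1), -1, 120.0),
    ],
)
def test_option_utility_closed_form(option, params, prev, expected):
    assert option_utility(option, params, prev) == pytest.approx(expected, abs=1e-9)


def test_softmax_closed_form():
    assert choice_prob_left(3.0, 3.0, 5.0) == pytest.approx(0.5, abs=1e-12)
    assert choice_prob_left(99.0, -7.0, 0.0) == pytest.approx(0.5, abs=1e-12)
    # 10-point gap at beta = 0.1/point: logistic at logit 1
    assert choice_prob_left(10.0, 0.0, 0.1) == pytest.approx(
        1.0 / (1.0 + math.exp(-1.0)), abs=1e-9
    )


def test_softmax_rejects_negative_beta():
    with pytest.raises(ValueError):
        choice_prob_left(1.0, 0.0, -0.1)
    with pytest.raises(ValueError):
        ModelParams(1.0, 0.0, -1.0)


def test_softmax_overflow_safe():
    p = choice_prob_left(1e6, -1e6, 10.0)
    assert 0.0 < p <= 1.0 and np.isfinite(p)


@settings(max_examples=100, derandomize=True)
@given(
    ua=st.floats(-500, 500),
    ub=st.floats(-500, 500),
    beta=st.floats(0, 2),
)
def test_softmax_complement_symmetry(ua, ub, beta):
    assert choice_prob_left(ua, ub, beta) + choice_prob_left(ub, ua, beta) == pytest.approx(
        1.0, abs=1e-12
    )


@settings(max_examples=100, derandomize=True)
@given(
    p=st.floats(0.05, 0.95),
    wm=st.floats(10, 200),
    lm=st.floats(10, 200),
    lam1=st.floats(-2, 2),
    dlam=st.floats(0.01, 2),
    prev=st.sampled_from([-1, 0, 1]),
)
def test_utility_strictly_decreasing_in_loss_sensitivity(p, wm, lm, lam1, dlam, prev):
    """Raising lambda lowers any option's utility when a loss is possible."""
    o = GambleOption(p, wm, lm)
    u1 = option_utility(o, ModelParams(lam1, 0.0, 0.1), prev)
    u2 = option_utility(o, ModelParams(lam1 + dlam, 0.0, 0.1), prev)
    assert u2 < u1


def test_gamma_zero_ignores_history():
    params = ModelParams(0.8, 0.0, 0.1)
    utils = {s: option_utility(OPT, params, s) for s in (-1, 0, 1)}
    assert len(set(utils.values())) == 1


def _one_trial_session(chose="L"):
    # two sure-win wheels 10 points apart: p(left) = expit(beta * 10)
    left = GambleOption(1.0, 60, 10)
    right = GambleOption(1.0, 50, 10)
    outcome = 60 if chose == "L" else 50
    return SessionData(
        "p1", "low_mdq", 1, [TrialRecord(left, right, 0, chose, outcome, 1)]
    )


def test_session_log_likelihood_closed_form(rng):
    sess = generate_session(ModelParams(1.0, 0.3, 0.0), 20, rng=rng)
    assert session_log_likelihood(sess, ModelParams(1.0, 0.3, 0.0)) == pytest.approx(
        20 * math.log(0.5), abs=1e-9
    )
    one = _one_trial_session("L")
    ll = session_log_likelihood(one, ModelParams(1.0, 0.0, 0.1))
    assert ll == pytest.approx(math.log(1.0 / (1.0 + math.exp(-1.0))), abs=1e-9)
    assert ll <= 0


def test_session_log_likelihood_brute_force_oracle(rng):
    """Vectorised likelihood equals an independent per-trial product."""
    for _ in range(100):
        params = ModelParams(
            float(rng.normal(1, 0.7)),
            float(rng.normal(0, 0.4)),
            float(np.exp(rng.normal(np.log(0.1), 0.7))),
        )
        sess = generate_session(params, int(rng.integers(5, 25)), rng=rng)
        expected = 0.0
        prev = 0
        for tr in sess.trials:  # plain scalar re-derivation
            w = params.loss_sensitivity + params.outcome_history * prev
            ul = tr.left.win_prob * tr.left.win_mag - w * (1 - tr.left.win_prob) * tr.left.loss_mag
            ur = tr.right.win_prob * tr.right.win_mag - w * (1 - tr.right.win_prob) * tr.right.loss_mag
            p_left = 1.0 / (1.0 + math.exp(params.inverse_temperature * (ur - ul)))
            p_obs = p_left if tr.choice_side == "L" else 1.0 - p_left
            expected += math.log(max(p_obs, 1e-12))
            prev = int(np.sign(tr.realized_outcome))
        assert session_log_likelihood(sess, params) == pytest.approx(expected, abs=1e-9)


def test_likelihood_invariant_to_joint_left_right_relabel(rng):
    params = ModelParams(0.9, 0.4, 0.15)
    sess = generate_session(params, 20, rng=rng)
    flipped = SessionData(
        sess.participant_id,
        sess.group,
        sess.day_index,
        [
            TrialRecord(
                t.right, t.left, t.prev_outcome_sign,
                "R" if t.choice_side == "L" else "L",
                t.realized_outcome, t.trial_index,
            )
            for t in sess.trials
        ],
    )
    assert session_log_likelihood(flipped, params) == pytest.approx(
        session_log_likelihood(sess, params), abs=1e-9
    )


def test_session_integrity_checks(rng):
    sess = generate_session(ModelParams(1.0, 0.0, 0.1), 10, rng=rng)
    sess.trials[4].prev_outcome_sign = -sess.trials[4].prev_outcome_sign or 1
    with pytest.raises(ValueError, match="inconsistent"):
        session_log_likelihood(sess, ModelParams(1.0, 0.0, 0.1))
    with pytest.raises(ValueError, match="no trials"):
        session_log_likelihood(
            SessionData("p", "g", 1, []), ModelParams(1.0, 0.0, 0.1)
        )


def test_trial_record_outcome_must_match_chosen_option():
    left = GambleOption(0.5, 100, 50)
    right = GambleOption(0.5, 80, 40)
    with pytest.raises(ValueError):
        TrialRecord(left, right, 0, "L", 80, 1)  # 80 is the *right* option's win


def test_simulate_trial_limits(rng):
    left = GambleOption(1.0, 120, 30)
    right = GambleOption(1.0, 70, 30)
    # near-deterministic softmax: left utility 50 points higher at beta=10
    params = ModelParams(1.0, 0.0, 10.0)
    for _ in range(200):
        side, outcome = simulate_trial(left, right, params, 0, rng)
        assert side == "L"
        assert outcome == 120  # sure win pays the win magnitude


def test_simulate_trial_matches_softmax_probability(rng):
    """Monte-Carlo choice rate agrees with the closed-form probability."""
    left = GambleOption(1.0, 60, 10)
    right = GambleOption(1.0, 50, 10)
    params = ModelParams(1.0, 0.0, 0.1)
    p = 1.0 / (1.0 + math.exp(-1.0))
    n = 10_000
    hits = sum(simulate_trial(left, right, params, 0, rng)[0] == "L" for _ in range(n))
    se = math.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 3 * se
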