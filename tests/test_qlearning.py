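"""Tests of the five-parameter Q-learning model: hand-computed updates and
likelihoods, a naive brute-force likelihood oracle, softmax properties,
PE regressors and behavioural metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revmot.qlearning import (AgentPolicy, SubjectParameters,
                              choice_probability, group_anova, initial_state,
                              negative_log_likelihood, pe_series,
                              percent_correct, reinforcement, simulate_agent,
                              update)
from revmot.task import (MISSED, RandomPolicy, TaskConfig, TrialRecord,
                         simulate_session)


def _trial(t, choice, outcome, good="A"):
    return TrialRecord(t=t, good_stim=good, choice=choice, outcome=outcome,
                       correct=choice == good, reversal_after=False,
                       criterion_met=False)


# ---------------------------------------------------------------------------
# brute-force oracle: naive, trial-by-trial, no vectorization, no sharing
# with the implementation


def oracle_nll(alpha, kappa, rho_rew, rho_pun, q_init, trials,
               designated="A", literal=False):
    q = {"A": q_init if designated == "A" else 0.0,
         "B": q_init if designated == "B" else 0.0}
    total = 0.0
    for r in trials:
        if r.choice == MISSED:
            continue
        m = max(q["A"], q["B"])  # shift so the chosen-option softmax is exact
        p_choice = math.exp(q[r.choice] - m) / (
            math.exp(q["A"] - m) + math.exp(q["B"] - m))
        total -= math.log(p_choice)
        if r.outcome == "NONE":
            continue
        rew = rho_rew if r.outcome == "WIN" else rho_pun
        u = "B" if r.choice == "A" else "A"
        q[r.choice] = q[r.choice] + alpha * (rew - q[r.choice])
        if literal:
            q[u] = q[u] - kappa * alpha * (rew - q[u])
        else:
            q[u] = q[u] + kappa * alpha * (-rew - q[u])
    return total


# ---------------------------------------------------------------------------
# parameters and transforms


def test_parameter_domains_enforced():
    with pytest.raises(ValueError):
        SubjectParameters(alpha=1.2, kappa=0.5, rho_rew=1, rho_pun=-1, q_init=0)
    with pytest.raises(ValueError):
        SubjectParameters(alpha=0.5, kappa=0.5, rho_rew=-1, rho_pun=-1, q_init=0)
    with pytest.raises(ValueError):
        SubjectParameters(alpha=0.5, kappa=0.5, rho_rew=1, rho_pun=1, q_init=0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    alpha=st.floats(0.01, 0.99), kappa=st.floats(0.01, 0.99),
    rho_rew=st.floats(0.05, 10), rho_pun=st.floats(-10, -0.05),
    q_init=st.floats(-3, 3),
)
def test_transform_round_trip(alpha, kappa, rho_rew, rho_pun, q_init):
    p = SubjectParameters(alpha, kappa, rho_rew, rho_pun, q_init)
    back = SubjectParameters.from_unconstrained(p.to_unconstrained())
    assert back.to_array() == pytest.approx(p.to_array(), rel=1e-9, abs=1e-12)


def test_initial_state_and_first_choice_probability():
    p = SubjectParameters(0.5, 0.5, 1.0, -1.0, q_init=0.3)
    q = initial_state(p, "A")
    assert q.tolist() == [0.3, 0.0]
    assert choice_probability(q)[0] == pytest.approx(1 / (1 + math.exp(-0.3)),
                                                     abs=1e-4)
    p0 = SubjectParameters(0.5, 0.5, 1.0, -1.0, q_init=1e-12)
    assert choice_probability(initial_state(p0, "B"))[0] == pytest.approx(0.5)


def test_reinforcement_is_the_free_magnitude():
    p = SubjectParameters(0.5, 0.5, 2.5, -1.0, 0.0)
    assert reinforcement("WIN", p) == 2.5
    assert reinforcement("LOSS", p) == -1.0
    with pytest.raises(ValueError):
        reinforcement("NONE", p)


# ---------------------------------------------------------------------------
# value update


def test_update_hand_computed_single():
    p = SubjectParameters(0.5, 1e-9, 1.0, -1.0, 0.0)
    q, dc, _ = update(np.zeros(2), "A", "WIN", p)
    assert dc == pytest.approx(1.0)
    assert q.tolist() == pytest.approx([0.5, 0.0], abs=1e-8)


def test_update_hand_computed_double_counterfactual():
    p = SubjectParameters(0.5, 1 - 1e-12, 1.0, -1.0, 0.0)
    q, dc, du = update(np.zeros(2), "A", "WIN", p)
    assert q.tolist() == pytest.approx([0.5, -0.5])
    assert choice_probability(q)[0] == pytest.approx(1 / (1 + math.exp(-1)),
                                                     abs=1e-4)


def test_kappa_zero_reduces_to_single_update():
    """With kappa -> 0 the unchosen value never moves, in either mode."""
    p = SubjectParameters(0.7, 1e-15, 2.0, -1.5, 0.4)
    q0 = np.array([0.3, -0.2])
    for literal in (False, True):
        q1, _, _ = update(q0, "A", "LOSS", p, literal=literal)
        assert q1[1] == pytest.approx(q0[1], abs=1e-12)
        q2, _, _ = update(q0, "B", "WIN", p, literal=literal)
        assert q2[0] == pytest.approx(q0[0], abs=1e-12)


def test_alpha_zero_limit_freezes_values():
    p = SubjectParameters(1e-12, 0.5, 1.0, -1.0, 0.25)
    q0 = initial_state(p, "A")
    q1, _, _ = update(q0, "A", "WIN", p)
    assert q1 == pytest.approx(q0, abs=1e-10)


def test_update_rejects_missed_trials():
    p = SubjectParameters(0.5, 0.5, 1.0, -1.0, 0.0)
    with pytest.raises(ValueError):
        update(np.zeros(2), MISSED, "WIN", p)
    with pytest.raises(ValueError):
        update(np.zeros(2), "A", "NONE", p)


def test_counterfactual_values_bounded_literal_not():
    """Counterfactual double update keeps Q inside the reinforcement
    range; the literal printed unchosen update can escape it."""
    p = SubjectParameters(0.9, 0.95, 1.0, -1.0, 0.0)
    lo, hi = min(p.rho_pun, -p.rho_rew), max(p.rho_rew, -p.rho_pun)
    q = np.zeros(2)
    rng = np.random.default_rng(0)
    max_literal = 0.0
    ql = np.zeros(2)
    for _ in range(400):
        ch = "A" if rng.random() < 0.5 else "B"
        out = "WIN" if rng.random() < 0.5 else "LOSS"
        q, _, _ = update(q, ch, out, p)
        assert lo - 1e-9 <= q.min() and q.max() <= hi + 1e-9
        ql, _, _ = update(ql, "A", "WIN", p, literal=True)
        max_literal = max(max_literal, float(np.abs(ql).max()))
    assert max_literal > hi  # repelling fixed point escapes the range


# ---------------------------------------------------------------------------
# softmax


def test_softmax_values_and_overflow_safety():
    assert choice_probability(np.array([0.5, 0.0]))[0] == pytest.approx(
        1 / (1 + math.exp(-0.5)), abs=1e-4)
    p = choice_probability(np.array([1000.0, 0.0]))
    assert p[0] == 1.0 and p[1] == 0.0
    with pytest.raises(FloatingPointError):
        choice_probability(np.array([np.nan, 0.0]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(qa=st.floats(-30, 30), qb=st.floats(-30, 30), c=st.floats(-20, 20))
def test_softmax_sums_to_one_and_translation_invariant(qa, qb, c):
    p = choice_probability(np.array([qa, qb]))
    assert p.sum() == pytest.approx(1.0)
    p_shift = choice_probability(np.array([qa + c, qb + c]))
    assert p_shift == pytest.approx(p, abs=1e-12)


# ---------------------------------------------------------------------------
# likelihood


def test_nll_three_trial_worked_example():
    """p = (0.5, sigmoid(0.5), sigmoid(-0.25)) for choices A,A,A after
    WIN then LOSS; total NLL = 1.9934 nats."""
    p = SubjectParameters(0.5, 1e-12, 1.0, -1.0, 1e-15)
    trials = [_trial(1, "A", "WIN"), _trial(2, "A", "LOSS"),
              _trial(3, "A", "WIN")]
    expected = (math.log(2) + math.log(1 + math.exp(-0.5))
                + math.log(1 + math.exp(0.25)))
    assert expected == pytest.approx(1.9933, abs=1e-3)
    assert negative_log_likelihood(p, trials) == pytest.approx(expected, abs=1e-8)


def test_nll_chance_level_for_flat_values():
    p = SubjectParameters(0.5, 0.5, 1e-8, -1e-8, 1e-15)
    trials = simulate_session(TaskConfig(n_trials=200), RandomPolicy(), 4)
    n_valid = sum(r.choice != MISSED for r in trials)
    assert negative_log_likelihood(p, trials) == pytest.approx(
        n_valid * math.log(2), rel=1e-6)


@pytest.mark.parametrize("literal", [False, True])
def test_nll_matches_brute_force_oracle(literal):
    """100 random parameter/session draws agree with a naive pure-Python
    pass to 1e-10."""
    rng = np.random.default_rng(11)
    cfg = TaskConfig(n_trials=80, miss_prob=0.05)
    for _ in range(100):
        p = SubjectParameters(
            alpha=rng.uniform(0.05, 0.95), kappa=rng.uniform(0.05, 0.95),
            rho_rew=rng.uniform(0.2, 3.0), rho_pun=-rng.uniform(0.2, 3.0),
            q_init=rng.normal(0, 0.5),
        )
        trials = simulate_session(cfg, RandomPolicy(), int(rng.integers(1 << 30)))
        ours = negative_log_likelihood(p, trials, literal=literal)
        ref = oracle_nll(p.alpha, p.kappa, p.rho_rew, p.rho_pun, p.q_init,
                         trials, literal=literal)
        assert ours == pytest.approx(ref, abs=1e-10)


def test_nll_requires_trials():
    p = SubjectParameters(0.5, 0.5, 1.0, -1.0, 0.0)
    with pytest.raises(ValueError):
        negative_log_likelihood(p, [])


# ---------------------------------------------------------------------------
# prediction-error regressor


def test_pe_series_matches_hand_oracle():
    p = SubjectParameters(0.5, 1e-12, 1.0, -1.0, 1e-15)
    trials = [_trial(1, "A", "WIN"), _trial(2, "A", "LOSS"),
              _trial(3, "A", "WIN")]
    d = pe_series(p, trials)
    assert d[0] == pytest.approx(1.0)       # R - q_init, independent of alpha
    assert d[1] == pytest.approx(-1.5)      # -1 - 0.5
    assert d[2] == pytest.approx(1.25)      # 1 - (-0.25)


def test_first_pe_independent_of_alpha():
    trials = [_trial(1, "A", "WIN")]
    for a in (0.1, 0.5, 0.9):
        p = SubjectParameters(a, 0.5, 1.0, -1.0, 0.3)
        assert pe_series(p, trials)[0] == pytest.approx(0.7)


def test_pe_series_nan_on_missed(default_params):
    trials = [_trial(1, "A", "WIN"), _trial(2, MISSED, "NONE"),
              _trial(3, "A", "WIN")]
    d = pe_series(default_params, trials)
    assert np.isnan(d[1]) and not np.isnan(d[0]) and not np.isnan(d[2])


# ---------------------------------------------------------------------------
# generative behaviour


def test_agent_with_strong_learning_beats_chance():
    p = SubjectParameters(0.9, 0.5, 3.0, -3.0, 0.0)
    trials = simulate_agent(p, TaskConfig(n_trials=600), rng_seed=6)
    assert percent_correct(trials) > 0.6


def test_agent_with_flat_values_is_at_chance():
    p = SubjectParameters(0.5, 0.5, 1e-9, -1e-9, 1e-15)
    trials = simulate_agent(p, TaskConfig(n_trials=2000), rng_seed=7)
    assert percent_correct(trials) == pytest.approx(0.5, abs=0.05)


def test_agent_reproducible_under_seed(default_params):
    a = simulate_agent(default_params, TaskConfig(), rng_seed=9)
    b = simulate_agent(default_params, TaskConfig(), rng_seed=9)
    assert a == b


# ---------------------------------------------------------------------------
# behavioural metrics


def test_percent_correct_counts_only_valid_trials():
    trials = [_trial(1, "A", "WIN"), _trial(2, "B", "LOSS"),
              _trial(3, MISSED, "NONE")]
    assert percent_correct(trials) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        percent_correct([_trial(1, MISSED, "NONE")])


def test_group_anova_against_textbook_fixture():
    """Three-group fixture; F verified against the standard one-way
    ANOVA decomposition computed by hand (between/within mean squares)."""
    g1 = [6.0, 8.0, 4.0, 5.0, 3.0, 4.0]
    g2 = [8.0, 12.0, 9.0, 11.0, 6.0, 8.0]
    g3 = [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]
    f, p = group_anova([g1, g2, g3])
    assert f == pytest.approx(9.264, abs=2e-3)
    assert 0.001 < p < 0.01


def test_group_anova_identical_groups_f_zero():
    g = [1.0, 2.0, 3.0]
    f, p = group_anova([g, list(g), list(g)])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_group_anova_validates_input():
    with pytest.raises(ValueError):
        group_anova([[1.0, 2.0]])
    with pytest.raises(ValueError):
        group_anova([[1.0, 2.0], [3.0]])


def test_group_anova_null_p_values_roughly_uniform():
    """Random regrouping of one pooled sample gives ~uniform p-values."""
    rng = np.random.default_rng(15)
    pooled = rng.normal(size=30)
    ps = []
    for _ in range(400):
        perm = rng.permutation(pooled)
        _, p = group_anova([perm[:10], perm[10:20], perm[20:]])
        ps.append(p)
    from scipy.stats import kstest

    assert kstest(ps, "uniform").pvalue > 0.01
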