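"""Tests of the empirical-prior EM fit: MAP estimation, prior moment
updates, Monte-Carlo model evidence and the exclusion rules."""

import numpy as np
import pytest

from revmot.hierarchical import (PriorHyper, SubjectFit, apply_exclusions,
                                 em_loop, map_estimate, model_evidence)
from revmot.qlearning import SubjectParameters, percent_correct
from revmot.task import RandomPolicy, TaskConfig, simulate_session
from revmot.qlearning import simulate_agent

TRUE_PARAMS = SubjectParameters(alpha=0.45, kappa=0.4, rho_rew=1.6,
                                rho_pun=-1.6, q_init=0.1)


def _informative_session(seed, n_trials=300):
    return simulate_agent(TRUE_PARAMS, TaskConfig(n_trials=n_trials), seed)


def test_prior_validation():
    with pytest.raises(ValueError):
        PriorHyper(np.zeros(5), np.zeros(5))
    with pytest.raises(ValueError):
        PriorHyper(np.zeros(4), np.ones(4))


def test_map_with_tight_prior_returns_prior_mean():
    mu = np.array([-0.5, 0.3, 0.2, 0.1, 0.05])
    prior = PriorHyper(mu, np.full(5, 1e-10))
    trials = _informative_session(0, 150)
    theta, hess, ok = map_estimate(trials, prior, n_restarts=2, rng_seed=1)
    assert theta == pytest.approx(mu, abs=1e-3)


def test_map_beats_random_prior_draws():
    """The penalized objective at the MAP is no worse than at 50 random
    prior draws."""
    from revmot.hierarchical import _Session, _penalized

    prior = PriorHyper.default()
    trials = _informative_session(3)
    theta, _, _ = map_estimate(trials, prior, n_restarts=5, rng_seed=2)
    sess = _Session(trials)
    at_map = _penalized(theta, sess, prior)
    rng = np.random.default_rng(4)
    for draw in prior.sample(50, rng):
        assert at_map <= _penalized(draw, sess, prior) + 1e-6


def test_map_laplace_interval_covers_truth():
    """With 300 trials and a weak prior, the Laplace 95% interval around
    the MAP covers the generating unconstrained parameters most of the
    time (checked on the learning-rate coordinate)."""
    prior = PriorHyper(np.zeros(5), np.full(5, 4.0))
    true_theta = TRUE_PARAMS.to_unconstrained()
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        trials = _informative_session(100 + seed)
        theta, hess, _ = map_estimate(trials, prior, n_restarts=3, rng_seed=seed)
        sd = np.sqrt(np.diag(np.linalg.inv(hess)))
        if abs(theta[0] - true_theta[0]) <= 1.96 * sd[0]:
            hits += 1
    assert hits >= 0.8 * n_rep


def test_evidence_degenerate_prior_equals_loglik():
    trials = _informative_session(7, 100)
    theta0 = TRUE_PARAMS.to_unconstrained()
    prior = PriorHyper(theta0, np.full(5, 1e-12))
    from revmot.qlearning import negative_log_likelihood

    ev = model_evidence(trials, prior, n_samples=1000, rng_seed=0)
    assert ev == pytest.approx(-negative_log_likelihood(TRUE_PARAMS, trials),
                               abs=1e-6)


def test_evidence_random_choices_near_chance_and_screen_fails():
    """Coin-flip choice data: evidence ~ n*log(0.5), so the
    better-than-chance screen rejects in >=95% of replicates."""
    prior = PriorHyper.default()
    n_fail = 0
    n_rep = 40
    for seed in range(n_rep):
        trials = simulate_session(TaskConfig(n_trials=150), RandomPolicy(), seed)
        ev = model_evidence(trials, prior, n_samples=2000, rng_seed=seed)
        if ev <= 150 * np.log(0.5):
            n_fail += 1
    assert n_fail >= 0.95 * n_rep


def test_evidence_informative_subjects_pass_screen():
    prior = PriorHyper.default()
    n_pass = 0
    n_rep = 40
    for seed in range(n_rep):
        trials = _informative_session(300 + seed, 150)
        ev = model_evidence(trials, prior, n_samples=2000, rng_seed=seed)
        if ev > 150 * np.log(0.5):
            n_pass += 1
    assert n_pass >= 0.95 * n_rep


def test_evidence_monte_carlo_consistency():
    """Doubling the sample count shrinks the between-seed spread."""
    trials = _informative_session(9, 200)
    prior = PriorHyper.default()

    def spread(n_samples):
        vals = [model_evidence(trials, prior, n_samples, rng_seed=s)
                for s in range(12)]
        return np.std(vals)

    assert spread(8000) < spread(1000)


def test_evidence_requires_samples():
    with pytest.raises(ValueError):
        model_evidence(_informative_session(1, 50), PriorHyper.default(),
                       n_samples=0)


# ---------------------------------------------------------------------------
# EM loop


def _cohort_sessions(n_subjects, seed, n_trials=200):
    rng = np.random.default_rng(seed)
    sessions = {}
    truths = {}
    for i in range(n_subjects):
        p = SubjectParameters(
            alpha=float(np.clip(rng.normal(0.45, 0.12), 0.05, 0.9)),
            kappa=float(np.clip(rng.normal(0.4, 0.1), 0.05, 0.9)),
            rho_rew=float(np.clip(rng.normal(1.6, 0.3), 0.3, 4)),
            rho_pun=float(-np.clip(rng.normal(1.6, 0.3), 0.3, 4)),
            q_init=float(rng.normal(0, 0.2)),
        )
        sid = f"S{i:02d}"
        truths[sid] = p
        sessions[sid] = simulate_agent(p, TaskConfig(n_trials=n_trials),
                                       int(rng.integers(1 << 30)))
    return sessions, truths


def test_em_requires_two_subjects():
    sessions, _ = _cohort_sessions(1, 0)
    with pytest.raises(ValueError):
        em_loop(sessions)


def test_em_identical_subjects_shrinks_prior_variance():
    """Duplicating one subject's trials: between-subject MAP variance is
    ~0, so prior variance falls toward the posterior-variance term and
    mu approaches the shared MAP."""
    base, _ = _cohort_sessions(1, 5, 250)
    trials = next(iter(base.values()))
    sessions = {f"S{i}": trials for i in range(6)}
    res = em_loop(sessions, max_iter=25, rng_seed=0, evidence_samples=500)
    thetas = np.array([f.theta_map for f in res.fits])
    assert np.allclose(thetas, thetas[0], atol=1e-2)
    assert np.allclose(res.prior.mu, thetas.mean(axis=0), atol=1e-2)
    mean_post_var = np.array([f.posterior_var for f in res.fits]).mean(axis=0)
    assert np.all(res.prior.sigma2 <= mean_post_var * 1.5 + 1e-3)


def test_em_recovery_and_monotone_objective():
    """Moderate cohort: recovered prior mean close to the transformed
    group mean for alpha, per-subject alpha correlates with truth, and
    the evidence lower bound is non-decreasing (with optimizer slack)."""
    sessions, truths = _cohort_sessions(25, 7, 300)
    res = em_loop(sessions, max_iter=40, rng_seed=1, evidence_samples=500)
    true_theta0 = np.array([truths[sid].to_unconstrained()[0]
                            for sid in sessions])
    assert abs(res.prior.mu[0] - true_theta0.mean()) < 0.25
    fit_alpha = np.array([f.params_map.alpha for f in res.fits])
    true_alpha = np.array([truths[f.subject_id].alpha for f in res.fits])
    assert np.corrcoef(fit_alpha, true_alpha)[0, 1] >= 0.6
    deltas = np.diff(res.objective_trace)
    assert np.all(deltas > -1.0)
    assert res.objective_trace[-1] > res.objective_trace[0]


# ---------------------------------------------------------------------------
# exclusions


def _dummy_fit(sid, n_valid=100, log_ev=-30.0):
    return SubjectFit(
        subject_id=sid, theta_map=np.zeros(5),
        params_map=SubjectParameters(0.5, 0.5, 1.0, -1.0, 0.0),
        posterior_var=np.ones(5), hessian=np.eye(5), nll_map=50.0,
        log_evidence=log_ev, n_valid_trials=n_valid, converged=True,
    )


def test_exclusion_planted_outlier_flagged():
    rng = np.random.default_rng(2)
    perfs = {f"S{i}": float(np.clip(rng.normal(0.75, 0.02), 0, 1))
             for i in range(30)}
    fits = [_dummy_fit(sid) for sid in perfs]
    mean, sd = np.mean(list(perfs.values())), np.std(list(perfs.values()), ddof=1)
    perfs["OUT"] = mean - 5 * sd
    fits.append(_dummy_fit("OUT"))
    flagged = [f.subject_id for f in apply_exclusions(fits, perfs)
               if f.excluded_low_performance]
    assert flagged == ["OUT"]


def test_exclusion_equal_performance_flags_nobody():
    perfs = {f"S{i}": 0.8 for i in range(10)}
    fits = [_dummy_fit(sid) for sid in perfs]
    assert not any(f.excluded_low_performance
                   for f in apply_exclusions(fits, perfs))


def test_exclusion_needs_cohort():
    with pytest.raises(ValueError):
        apply_exclusions([_dummy_fit("S0")], {"S0": 0.5})


def test_better_than_chance_rule_is_evidence_vs_chance():
    f = _dummy_fit("S0", n_valid=100, log_ev=100 * np.log(0.5) + 1.0)
    f.better_than_chance = f.log_evidence > f.chance_log_lik
    assert f.better_than_chance
    g = _dummy_fit("S1", n_valid=100, log_ev=100 * np.log(0.5) - 1.0)
    g.better_than_chance = g.log_evidence > g.chance_log_lik
    assert not g.better_than_chance
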