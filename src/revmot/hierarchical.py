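"""Hierarchical empirical-prior fitting of the Q-learning model.

Subjects are fitted jointly under a group-level Gaussian prior on the
unconstrained parameter scale.  The fit alternates MAP estimation per
subject (with a Laplace approximation of the posterior) and a moment
update of the prior mean and diagonal variance — the empirical-prior
expectation-maximization recipe common in computational psychiatry.
Per-subject model evidence is approximated by Monte-Carlo integration of
the likelihood over prior samples and screens subjects whose choices are
explained no better than chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import _kernels
from .qlearning import (N_PARAMS, SubjectParameters, encode_trials,
                        natural_from_unconstrained, percent_correct)
from .task import STIMULI, TrialRecord

log = logging.getLogger(__name__)

DEFAULT_PRIOR_MU = np.zeros(N_PARAMS)
DEFAULT_PRIOR_SIGMA2 = np.full(N_PARAMS, 6.25)  # SD 2.5, weakly informative
SIGMA2_FLOOR = 1e-4
HESS_STEP = 1e-4
EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class PriorHyper:
    """Group-level Gaussian prior (mean, diagonal variance) on R^5."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        s2 = np.asarray(self.sigma2, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", s2)
        if mu.shape != (N_PARAMS,) or s2.shape != (N_PARAMS,):
            raise ValueError("prior hyperparameters must be 5-vectors")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(s2))):
            raise ValueError("prior hyperparameters must be finite")
        if np.any(s2 <= 0):
            raise ValueError("prior variances must be strictly positive")

    @staticmethod
    def default() -> "PriorHyper":
        return PriorHyper(DEFAULT_PRIOR_MU.copy(), DEFAULT_PRIOR_SIGMA2.copy())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, np.sqrt(self.sigma2), size=(n, N_PARAMS))


@dataclass
class SubjectFit:
    subject_id: str
    theta_map: np.ndarray
    params_map: SubjectParameters
    posterior_var: np.ndarray        # diagonal of Laplace covariance
    hessian: np.ndarray              # curvature of penalized objective at MAP
    nll_map: float                   # data NLL at the MAP (no prior term)
    log_evidence: float
    n_valid_trials: int
    converged: bool
    better_than_chance: bool = True
    excluded_low_performance: bool = False

    @property
    def chance_log_lik(self) -> float:
        return self.n_valid_trials * np.log(0.5)


class _Session:
    """Pre-encoded session for repeated likelihood evaluation."""

    __slots__ = ("choices", "outcomes", "n_valid", "designated", "literal")

    def __init__(self, trials: Sequence[TrialRecord], designated_stim: str = "A",
                 literal: bool = False) -> None:
        self.choices, self.outcomes = encode_trials(trials)
        self.n_valid = int(np.sum(self.choices >= 0))
        self.designated = STIMULI.index(designated_stim)
        self.literal = literal

    def nll_nat(self, nat: np.ndarray) -> float:
        scratch = np.empty(len(self.choices))
        return float(
            _kernels.nll_kernel(
                self.choices, self.outcomes,
                nat[0], nat[1], nat[2], nat[3], nat[4],
                self.designated, self.literal, scratch,
            )
        )

    def nll_theta(self, theta: np.ndarray) -> float:
        return self.nll_nat(natural_from_unconstrained(theta)[0])

    def nll_grad_theta(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """NLL and gradient in unconstrained space (chain rule over the
        natural-parameter transform)."""
        nat = natural_from_unconstrained(theta)[0]
        nll, g_nat = _kernels.nll_grad_kernel(
            self.choices, self.outcomes,
            nat[0], nat[1], nat[2], nat[3], nat[4],
            self.designated, self.literal,
        )
        jac = np.array([
            nat[0] * (1.0 - nat[0]),   # d alpha / d theta0
            nat[1] * (1.0 - nat[1]),   # d kappa / d theta1
            nat[2],                    # d rho_rew / d theta2
            nat[3],                    # d rho_pun / d theta3 (= -exp)
            1.0,
        ])
        return float(nll), g_nat * jac


def _penalized(theta: np.ndarray, sess: _Session, prior: PriorHyper) -> float:
    dev = theta - prior.mu
    pen = 0.5 * float(np.sum(dev * dev / prior.sigma2))
    val = sess.nll_theta(theta) + pen
    return val if np.isfinite(val) else 1e12


def _penalized_grad(theta: np.ndarray, sess: _Session,
                    prior: PriorHyper) -> tuple[float, np.ndarray]:
    dev = (theta - prior.mu) / prior.sigma2
    nll, g = sess.nll_grad_theta(theta)
    val = nll + 0.5 * float(np.sum(dev * (theta - prior.mu)))
    grad = g + dev
    if not (np.isfinite(val) and np.all(np.isfinite(grad))):
        return 1e12, np.zeros_like(theta)
    return val, grad


def _fd_hessian(f, x: np.ndarray, step: float = HESS_STEP) -> np.ndarray:
    """Central finite-difference Hessian, symmetrized."""
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        h[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return 0.5 * (h + h.T)


def _repair_pd(h: np.ndarray, floor: float = EIG_FLOOR) -> tuple[np.ndarray, bool]:
    """Floor eigenvalues to make the curvature positive-definite."""
    vals, vecs = np.linalg.eigh(h)
    if np.all(vals > floor):
        return h, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True


def map_estimate(
    trials: Sequence[TrialRecord],
    prior: PriorHyper,
    n_restarts: int = 5,
    rng_seed: int = 0,
    x0: Optional[np.ndarray] = None,
    designated_stim: str = "A",
    literal: bool = False,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """MAP estimate in unconstrained space plus Laplace curvature.

    Runs local optimizations from the prior mean (or ``x0`` if given)
    and ``n_restarts - 1`` prior draws, keeps the best penalized
    optimum, and returns (theta_map, hessian, converged).  The Hessian
    is the curvature of the penalized objective, repaired to be
    positive-definite when needed.
    """
    sess = _Session(trials, designated_stim, literal)
    return _map_estimate_session(sess, prior, n_restarts, rng_seed, x0)


def _map_estimate_session(
    sess: _Session,
    prior: PriorHyper,
    n_restarts: int,
    rng_seed: int,
    x0: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    rng = np.random.default_rng(rng_seed)
    starts = [prior.mu.copy() if x0 is None else np.asarray(x0, dtype=float)]
    if n_restarts > 1:
        starts.extend(prior.sample(n_restarts - 1, rng))
    best = None
    any_success = False
    for s in starts:
        res = minimize(
            _penalized_grad, s, args=(sess, prior), jac=True,
            method="L-BFGS-B", options={"maxiter": 500},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    theta = np.asarray(best.x, dtype=float)
    if not any_success:
        log.warning("MAP optimizer did not report convergence on any restart")
    hess = _fd_hessian(lambda t: _penalized(t, sess, prior), theta)
    hess, repaired = _repair_pd(hess)
    if repaired:
        log.debug("Hessian repaired to positive-definite")
    return theta, hess, any_success


def model_evidence(
    trials: Sequence[TrialRecord],
    prior: PriorHyper,
    n_samples: int = 10_000,
    rng_seed: int = 0,
    designated_stim: str = "A",
    literal: bool = False,
) -> float:
    """Monte-Carlo marginal log-likelihood: log mean_k L(theta_k).

    theta_k are prior draws; the average uses a log-sum-exp so very
    small likelihoods do not underflow.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sess = _Session(trials, designated_stim, literal)
    rng = np.random.default_rng(rng_seed)
    thetas = prior.sample(n_samples, rng)
    nat = natural_from_unconstrained(thetas)
    nlls = _kernels.nll_batch(sess.choices, sess.outcomes, nat,
                              sess.designated, sess.literal)
    logliks = -nlls
    if np.all(np.isneginf(logliks)):
        warnings.warn("all evidence samples underflowed; evidence is -inf")
        return float("-inf")
    return float(logsumexp(logliks) - np.log(n_samples))


@dataclass
class EMResult:
    prior: PriorHyper
    fits: list[SubjectFit]
    n_iter: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def em_loop(
    sessions: dict[str, Sequence[TrialRecord]],
    init_prior: Optional[PriorHyper] = None,
    tol: float = 1e-3,
    max_iter: int = 100,
    n_restarts: int = 5,
    rng_seed: int = 0,
    evidence_samples: int = 10_000,
    designated_stim: str = "A",
    literal: bool = False,
) -> EMResult:
    """Empirical-prior EM over a cohort.

    E-step: per-subject MAP + Laplace covariance under the current
    prior (warm-started from the previous iterate after iteration 1).
    M-step: mu_j = mean_i theta_ij; sigma2_j = mean_i(theta_ij^2 +
    var_ij) - mu_j^2, floored at a small positive constant.  Stops when
    max |dmu| < tol.  Model evidence is computed under the final prior.
    """
    if len(sessions) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    prior = init_prior if init_prior is not None else PriorHyper.default()
    ids = list(sessions.keys())
    encoded = {sid: _Session(sessions[sid], designated_stim, literal) for sid in ids}
    seed_rng = np.random.default_rng(rng_seed)
    subj_seeds = {sid: int(seed_rng.integers(2**31 - 1)) for sid in ids}

    thetas = {sid: None for sid in ids}
    hessians: dict[str, np.ndarray] = {}
    converged = False
    objective_trace: list[float] = []
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        pvars = {}
        logdet_h = {}
        for sid in ids:
            restarts = n_restarts if it == 1 else (2 if it == 2 else 1)
            theta, hess, ok = _map_estimate_session(
                encoded[sid], prior, restarts,
                subj_seeds[sid] + it, x0=thetas[sid],
            )
            thetas[sid] = theta
            hessians[sid] = hess
            pvars[sid] = np.diag(np.linalg.inv(hess))
            logdet_h[sid] = float(np.linalg.slogdet(hess)[1])
        tmat = np.array([thetas[sid] for sid in ids])
        vmat = np.array([pvars[sid] for sid in ids])
        mu_new = tmat.mean(axis=0)
        s2_new = (tmat**2 + vmat).mean(axis=0) - mu_new**2
        floored = s2_new < SIGMA2_FLOOR
        if np.all(floored):
            warnings.warn("all prior variances collapsed to the floor; degenerate prior")
        s2_new = np.maximum(s2_new, SIGMA2_FLOOR)
        delta = np.max(np.abs(mu_new - prior.mu))
        prior = PriorHyper(mu_new, s2_new)
        # Laplace evidence lower bound under the updated prior:
        # sum_i [loglik_i + log N(theta_i; mu, sigma2) + entropy(q_i)]
        elbo = 0.0
        for sid in ids:
            dev = thetas[sid] - prior.mu
            log_prior = -0.5 * float(
                np.sum(dev * dev / prior.sigma2)
                + np.sum(np.log(2.0 * np.pi * prior.sigma2))
            )
            entropy = 0.5 * (N_PARAMS * np.log(2.0 * np.pi * np.e) - logdet_h[sid])
            elbo += -encoded[sid].nll_theta(thetas[sid]) + log_prior + entropy
        objective_trace.append(elbo)
        if delta < tol:
            converged = True
            break

    fits: list[SubjectFit] = []
    for sid in ids:
        sess = encoded[sid]
        theta = thetas[sid]
        ev = model_evidence(
            sessions[sid], prior, evidence_samples,
            rng_seed=subj_seeds[sid] ^ 0x5EED,
            designated_stim=designated_stim, literal=literal,
        )
        nll = sess.nll_theta(theta)
        fit = SubjectFit(
            subject_id=sid,
            theta_map=theta,
            params_map=SubjectParameters.from_unconstrained(theta),
            posterior_var=np.diag(np.linalg.inv(hessians[sid])),
            hessian=hessians[sid],
            nll_map=nll,
            log_evidence=ev,
            n_valid_trials=sess.n_valid,
            converged=True,
        )
        fit.better_than_chance = fit.log_evidence > fit.chance_log_lik
        fits.append(fit)
    return EMResult(prior=prior, fits=fits, n_iter=n_iter,
                    converged=converged, objective_trace=objective_trace)


def apply_exclusions(
    fits: Sequence[SubjectFit],
    performance: dict[str, float],
) -> list[SubjectFit]:
    """Flag subjects for exclusion.

    A subject is excluded for low performance when their percent correct
    falls more than three standard deviations below the cohort mean
    (computed once over the full cohort, not iterated); the
    better-than-chance flag comes from the evidence screen.
    """
    perfs = np.array([performance[f.subject_id] for f in fits], dtype=float)
    if len(perfs) < 2:
        raise ValueError("exclusion rule needs at least 2 subjects (SD undefined)")
    mean, sd = float(perfs.mean()), float(perfs.std(ddof=1))
    cutoff = mean - 3.0 * sd
    for f, p in zip(fits, perfs):
        f.excluded_low_performance = bool(p < cutoff)
    return list(fits)


def fits_to_frame(fits: Sequence[SubjectFit]):
    """Per-subject fit table (natural-space parameters, SDs, flags)."""
    import pandas as pd

    rows = []
    for f in fits:
        nat = f.params_map
        rows.append(
            {
                "subject_id": f.subject_id,
                "alpha": nat.alpha,
                "kappa": nat.kappa,
                "rho_rew": nat.rho_rew,
                "rho_pun": nat.rho_pun,
                "q_init": nat.q_init,
                **{
                    f"sd_theta_{name}": float(np.sqrt(v))
                    for name, v in zip(
                        ("alpha", "kappa", "rho_rew", "rho_pun", "q_init"),
                        f.posterior_var,
                    )
                },
                "nll": f.nll_map,
                "log_evidence": f.log_evidence,
                "n_valid_trials": f.n_valid_trials,
                "better_than_chance": f.better_than_chance,
                "excluded_low_performance": f.excluded_low_performance,
            }
        )
    return pd.DataFrame(rows)
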