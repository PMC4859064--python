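"""Five-parameter double-update Q-learning model of reversal learning.

The model maintains one expected value per stimulus.  After feedback R
(a free reward magnitude rho_rew > 0 for wins, rho_pun < 0 for losses)
the chosen option's value moves toward R by a fraction alpha of the
prediction error delta = R - Q_c.  The unchosen option is updated in the
opposite direction, weighted by kappa in (0,1), exploiting the task's
anticorrelated contingencies; a fifth parameter q_init offsets the
initial value of one designated stimulus.  Choices follow a unit-
temperature softmax on the value difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import _kernels
from .task import (MISSED, NONE, STIMULI, TaskConfig, Policy, TrialRecord,
                   simulate_session)

N_PARAMS = 5
PARAM_NAMES = ("alpha", "kappa", "rho_rew", "rho_pun", "q_init")

TRANSFORM_VERSION = "sigmoid-sigmoid-log-neglog-id/v1"


@dataclass(frozen=True)
class SubjectParameters:
    """Natural-space model parameters.

    alpha, kappa in (0,1); rho_rew > 0; rho_pun < 0; q_init unbounded.
    """

    alpha: float
    kappa: float
    rho_rew: float
    rho_pun: float
    q_init: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.0 < self.kappa < 1.0):
            raise ValueError(f"kappa must be in (0,1), got {self.kappa}")
        if not self.rho_rew > 0.0:
            raise ValueError(f"rho_rew must be positive, got {self.rho_rew}")
        if not self.rho_pun < 0.0:
            raise ValueError(f"rho_pun must be negative, got {self.rho_pun}")
        if not np.isfinite(self.q_init):
            raise ValueError("q_init must be finite")

    def to_unconstrained(self) -> np.ndarray:
        """Map to R^5: (logit a, logit k, log r+, log(-r-), q_init)."""
        return np.array(
            [
                logit(self.alpha),
                logit(self.kappa),
                np.log(self.rho_rew),
                np.log(-self.rho_pun),
                self.q_init,
            ]
        )

    @staticmethod
    def from_unconstrained(theta: np.ndarray) -> "SubjectParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_PARAMS,):
            raise ValueError(f"theta must have shape ({N_PARAMS},)")
        return SubjectParameters(
            alpha=float(expit(theta[0])),
            kappa=float(expit(theta[1])),
            rho_rew=float(np.exp(theta[2])),
            rho_pun=float(-np.exp(theta[3])),
            q_init=float(theta[4]),
        )

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.kappa, self.rho_rew, self.rho_pun, self.q_init])


def natural_from_unconstrained(theta: np.ndarray) -> np.ndarray:
    """Vectorised unconstrained -> natural map for (n, 5) arrays.

    Inputs are clipped to +/-40 so optimizer line-search probes far
    outside the plausible region cannot overflow the exponentials.
    """
    theta = np.clip(np.atleast_2d(np.asarray(theta, dtype=float)), -40.0, 40.0)
    nat = np.empty_like(theta)
    nat[:, 0] = expit(theta[:, 0])
    nat[:, 1] = expit(theta[:, 1])
    nat[:, 2] = np.exp(theta[:, 2])
    nat[:, 3] = -np.exp(theta[:, 3])
    nat[:, 4] = theta[:, 4]
    return nat


# ---------------------------------------------------------------------------
# Elementary model operations


def initial_state(params: SubjectParameters, designated_stim: str = "A") -> np.ndarray:
    """Initial Q-values: q_init on the designated stimulus, 0 on the other."""
    if designated_stim not in STIMULI:
        raise ValueError(f"designated stimulus must be one of {STIMULI}")
    q = np.zeros(2)
    q[STIMULI.index(designated_stim)] = params.q_init
    return q


def reinforcement(outcome: str, params: SubjectParameters) -> float:
    """Scalar reinforcement for a feedback event (never for NONE)."""
    if outcome == "WIN":
        return params.rho_rew
    if outcome == "LOSS":
        return params.rho_pun
    raise ValueError(f"no reinforcement event for outcome {outcome!r}")


def update(
    q: np.ndarray,
    choice: str,
    outcome: str,
    params: SubjectParameters,
    literal: bool = False,
) -> tuple[np.ndarray, float, float]:
    """One value update; returns (new q, chosen PE, unchosen PE).

    Default mode uses the stable counterfactual unchosen update
    delta_u = -R - Q_u, Q_u += kappa*alpha*delta_u.  ``literal=True``
    applies Q_u -= kappa*alpha*(R - Q_u) instead, which is not
    guaranteed to stay bounded.
    """
    if choice == MISSED or outcome == NONE:
        raise ValueError("update requires a non-missed trial with feedback")
    r = reinforcement(outcome, params)
    c = STIMULI.index(choice)
    u = 1 - c
    q = q.astype(float).copy()
    delta_c = r - q[c]
    q[c] += params.alpha * delta_c
    if literal:
        delta_u = r - q[u]
        q[u] -= params.kappa * params.alpha * delta_u
    else:
        delta_u = -r - q[u]
        q[u] += params.kappa * params.alpha * delta_u
    return q, delta_c, delta_u


def choice_probability(q: np.ndarray) -> np.ndarray:
    """Softmax choice probabilities (p_A, p_B), overflow-safe."""
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise FloatingPointError(f"non-finite Q-values: {q}")
    p_a = expit(q[0] - q[1])
    return np.array([p_a, 1.0 - p_a])


# ---------------------------------------------------------------------------
# Likelihood


def encode_trials(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Encode a session as integer arrays for the compiled kernel."""
    if len(trials) == 0:
        raise ValueError("empty session")
    choices = np.array(
        [-1 if r.choice == MISSED else STIMULI.index(r.choice) for r in trials],
        dtype=np.int64,
    )
    outcomes = np.array(
        [0 if r.outcome == NONE else (1 if r.outcome == "WIN" else -1) for r in trials],
        dtype=np.int64,
    )
    return choices, outcomes


def negative_log_likelihood(
    params: SubjectParameters,
    trials: Sequence[TrialRecord],
    designated_stim: str = "A",
    literal: bool = False,
) -> float:
    """Sum of -log p(observed choice) over non-missed trials."""
    choices, outcomes = encode_trials(trials)
    deltas = np.empty(len(choices))
    return float(
        _kernels.nll_kernel(
            choices, outcomes,
            params.alpha, params.kappa, params.rho_rew, params.rho_pun,
            params.q_init, STIMULI.index(designated_stim), literal, deltas,
        )
    )


def pe_series(
    params: SubjectParameters,
    trials: Sequence[TrialRecord],
    designated_stim: str = "A",
    literal: bool = False,
) -> np.ndarray:
    """Per-trial chosen-option prediction errors (NaN on missed trials).

    This is the single-trial regressor used as a parametric modulator in
    event-related analyses of feedback responses.
    """
    choices, outcomes = encode_trials(trials)
    deltas = np.empty(len(choices))
    _kernels.nll_kernel(
        choices, outcomes,
        params.alpha, params.kappa, params.rho_rew, params.rho_pun,
        params.q_init, STIMULI.index(designated_stim), literal, deltas,
    )
    return deltas


def pe_regressor_frame(
    params: SubjectParameters,
    trials: Sequence[TrialRecord],
    subject_id: str,
    **kwargs,
) -> pd.DataFrame:
    """PE series as a tidy frame (subject_id, t, delta); NaN -> NA on write."""
    deltas = pe_series(params, trials, **kwargs)
    return pd.DataFrame(
        {"subject_id": subject_id, "t": [r.t for r in trials], "delta": deltas}
    )


def write_pe_regressor(path, frames: Sequence[pd.DataFrame]) -> None:
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


# ---------------------------------------------------------------------------
# Generative use


class AgentPolicy(Policy):
    """Task policy that samples choices from the Q-learning model."""

    def __init__(
        self,
        params: SubjectParameters,
        designated_stim: str = "A",
        literal: bool = False,
    ) -> None:
        self.params = params
        self.designated_stim = designated_stim
        self.literal = literal
        self.q = initial_state(params, designated_stim)

    def reset(self, rng: np.random.Generator) -> None:
        self.q = initial_state(self.params, self.designated_stim)

    def choose(self, good_stim: str, rng: np.random.Generator) -> str:
        p = choice_probability(self.q)
        return STIMULI[0] if rng.random() < p[0] else STIMULI[1]

    def observe(self, choice: str, outcome: str) -> None:
        self.q, _, _ = update(self.q, choice, outcome, self.params, self.literal)


def simulate_agent(
    params: SubjectParameters,
    config: TaskConfig,
    rng_seed: int,
    designated_stim: str = "A",
    literal: bool = False,
) -> list[TrialRecord]:
    """Simulate a session with choices generated by the model itself."""
    policy = AgentPolicy(params, designated_stim, literal)
    return simulate_session(config, policy, rng_seed)


# ---------------------------------------------------------------------------
# Behavioural metrics


def percent_correct(trials: Sequence[TrialRecord]) -> float:
    """Proportion of correct responses among non-missed trials."""
    valid = [r for r in trials if r.choice != MISSED]
    if not valid:
        raise ValueError("all trials missed; percent correct undefined")
    return sum(r.correct for r in valid) / len(valid)


def group_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA over per-subject values grouped by class."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two subjects")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)
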