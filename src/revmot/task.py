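"""Criterion-triggered probabilistic reversal-learning task simulator.

Two stimuli (A, B); one is currently "good" and rewards with high
probability, the other with the complementary low probability.  Once the
subject has made at least ``criterion_correct`` correct choices within the
last ``criterion_window`` (non-missed) trials since the last reversal, the
contingency reverses with probability ``reversal_hazard`` after every
further trial on which the criterion holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STIMULI = ("A", "B")
MISSED = "MISSED"
WIN, LOSS, NONE = "WIN", "LOSS", "NONE"


class ConfigError(ValueError):
    """Raised for invalid task or cohort configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of the reversal task.

    Defaults give 300 trials, 80/20 reward contingencies, a 5-of-6
    sliding-window performance criterion and a 20% per-trial reversal
    hazard while the criterion holds, with ±10-cent feedback.
    """

    n_trials: int = 300
    p_reward_good: float = 0.80
    p_reward_bad: float = 0.20
    criterion_correct: int = 5
    criterion_window: int = 6
    reversal_hazard: float = 0.20
    win_amount: float = 0.10
    loss_amount: float = -0.10
    miss_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError(f"n_trials must be positive, got {self.n_trials}")
        if not (0.0 <= self.p_reward_bad <= self.p_reward_good <= 1.0):
            raise ConfigError(
                "need 0 <= p_reward_bad <= p_reward_good <= 1, got "
                f"({self.p_reward_bad}, {self.p_reward_good})"
            )
        if not (0 < self.criterion_correct <= self.criterion_window):
            raise ConfigError("criterion_correct must be in 1..criterion_window")
        if not (0.0 <= self.reversal_hazard <= 1.0):
            raise ConfigError(f"reversal_hazard must be a probability, got {self.reversal_hazard}")
        if not (0.0 <= self.miss_prob < 1.0):
            raise ConfigError(f"miss_prob must be in [0, 1), got {self.miss_prob}")


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the task.

    ``reversal_after`` marks that the contingency flips before the next
    trial; ``criterion_met`` is evaluated after this trial's feedback.
    """

    t: int                      # 1-based trial index
    good_stim: str              # currently better stimulus
    choice: str                 # "A", "B" or MISSED
    outcome: str                # WIN, LOSS or NONE
    correct: bool
    reversal_after: bool
    criterion_met: bool


class Policy:
    """Choice-policy contract for the simulator.

    ``reset`` is called once per session, ``choose`` before every trial
    (the oracle peeks at ``good_stim``; behavioural policies must not),
    and ``observe`` after feedback on non-missed trials.
    """

    def reset(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def choose(self, good_stim: str, rng: np.random.Generator) -> str:
        raise NotImplementedError

    def observe(self, choice: str, outcome: str) -> None:  # pragma: no cover - trivial
        pass


class OraclePolicy(Policy):
    """Always chooses the currently better stimulus."""

    def choose(self, good_stim: str, rng: np.random.Generator) -> str:
        return good_stim


class RandomPolicy(Policy):
    """Chooses uniformly at random."""

    def choose(self, good_stim: str, rng: np.random.Generator) -> str:
        return STIMULI[rng.integers(2)]


def simulate_session(
    config: TaskConfig, policy: Policy, rng_seed: int
) -> list[TrialRecord]:
    """Simulate one session of the reversal task.

    The criterion is evaluable only once at least ``criterion_window``
    non-missed trials have elapsed since the last reversal; while it
    holds, a reversal is drawn with probability ``reversal_hazard`` after
    every trial and resets the window.
    """
    rng = np.random.default_rng(rng_seed)
    policy.reset(rng)
    good = STIMULI[rng.integers(2)]
    window: list[bool] = []  # correctness of non-missed trials since last reversal
    records: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        if config.miss_prob > 0 and rng.random() < config.miss_prob:
            choice = MISSED
        else:
            choice = policy.choose(good, rng)
            if choice not in STIMULI:
                raise ValueError(f"policy returned invalid stimulus {choice!r}")
        if choice == MISSED:
            outcome = NONE
            correct = False
        else:
            correct = choice == good
            p_win = config.p_reward_good if correct else config.p_reward_bad
            outcome = WIN if rng.random() < p_win else LOSS
            policy.observe(choice, outcome)
            window.append(correct)
        criterion_met = (
            len(window) >= config.criterion_window
            and sum(window[-config.criterion_window:]) >= config.criterion_correct
        )
        reversal_after = bool(
            criterion_met and rng.random() < config.reversal_hazard
        )
        records.append(
            TrialRecord(
                t=t,
                good_stim=good,
                choice=choice,
                outcome=outcome,
                correct=correct,
                reversal_after=reversal_after,
                criterion_met=criterion_met,
            )
        )
        if reversal_after:
            good = STIMULI[1 - STIMULI.index(good)]
            window = []
    return records


@dataclass(frozen=True)
class SessionSummary:
    n_trials: int
    n_missed: int
    n_reversals: int
    percent_correct: Optional[float]       # None if every trial missed
    win_rate_given_correct: Optional[float]
    hazard_given_criterion: Optional[float]
    total_payout: float


def session_summary(
    trials: Sequence[TrialRecord],
    win_amount: float = 0.10,
    loss_amount: float = -0.10,
) -> SessionSummary:
    """Descriptive statistics of one session.

    ``percent_correct`` is over non-missed trials; the empirical hazard is
    reversals per criterion-met trial.  Undefined rates are reported as
    ``None`` rather than silently as 0.
    """
    if len(trials) == 0:
        raise ValueError("empty session")
    n_missed = sum(1 for r in trials if r.choice == MISSED)
    n_valid = len(trials) - n_missed
    n_correct = sum(1 for r in trials if r.correct)
    n_reversals = sum(1 for r in trials if r.reversal_after)
    n_crit = sum(1 for r in trials if r.criterion_met)
    n_win_correct = sum(1 for r in trials if r.correct and r.outcome == WIN)
    payout = sum(
        win_amount if r.outcome == WIN else (loss_amount if r.outcome == LOSS else 0.0)
        for r in trials
    )
    return SessionSummary(
        n_trials=len(trials),
        n_missed=n_missed,
        n_reversals=n_reversals,
        percent_correct=(n_correct / n_valid) if n_valid else None,
        win_rate_given_correct=(n_win_correct / n_correct) if n_correct else None,
        hazard_given_criterion=(n_reversals / n_crit) if n_crit else None,
        total_payout=payout,
    )


TRIAL_COLUMNS = [
    "subject_id",
    "t",
    "good_stim",
    "choice",
    "outcome",
    "correct",
    "criterion_met",
    "reversal_after",
]


def trials_to_frame(trials: Sequence[TrialRecord], subject_id: str) -> pd.DataFrame:
    """Tabular view of a session (MISSED encoded as NA on write)."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "t": [r.t for r in trials],
            "good_stim": [r.good_stim for r in trials],
            "choice": [r.choice for r in trials],
            "outcome": [r.outcome for r in trials],
            "correct": [int(r.correct) for r in trials],
            "criterion_met": [int(r.criterion_met) for r in trials],
            "reversal_after": [int(r.reversal_after) for r in trials],
        }
    )[TRIAL_COLUMNS]


def write_trials(path, sessions: dict[str, Sequence[TrialRecord]]) -> None:
    """Write sessions as one tab-separated file, one row per trial."""
    frames = [trials_to_frame(tr, sid) for sid, tr in sessions.items()]
    df = pd.concat(frames, ignore_index=True)
    df["choice"] = df["choice"].replace(MISSED, "NA")
    df["outcome"] = df["outcome"].replace(NONE, "NA")
    df.to_csv(path, sep="\t", index=False)


def read_trials(path) -> dict[str, list[TrialRecord]]:
    """Read a trial log written by :func:`write_trials`."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"trial log missing columns: {missing}")
    sessions: dict[str, list[TrialRecord]] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        recs = [
            TrialRecord(
                t=int(row.t),
                good_stim=str(row.good_stim),
                choice=MISSED if row.choice == "NA" else str(row.choice),
                outcome=NONE if row.outcome == "NA" else str(row.outcome),
                correct=bool(int(row.correct)),
                reversal_after=bool(int(row.reversal_after)),
                criterion_met=bool(int(row.criterion_met)),
            )
            for row in grp.itertuples(index=False)
        ]
        sessions[str(sid)] = recs
    return sessions
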