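"""Synthetic study cohort generator.

Produces every input the analysis pipeline consumes — questionnaire item
matrices, per-subject reversal-task choice logs, and ROI covariates —
with a planted four-class socio-motivational structure:

* class-specific parcel profiles (peer-dependent: PPM high / TPM low;
  teacher-dependent: PPM low / TPM high; peer-and-teacher-dependent:
  both high; independent: both low);
* class-dependent learning rates (lower alpha in the independent class
  than in the peer-and-teacher-dependent class);
* class-dependent ROI signals (left associative striatum elevated in the
  independent class, right PFC elevated in the peer-and-teacher-
  dependent class), generated directly as post-GLM scalar estimates.

Choice data are simulated from the Q-learning model itself on the
reversal task, so model fitting has a well-defined ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .latent import N_PPM_ITEMS, N_TPM_ITEMS, LCASolution
from .qlearning import SubjectParameters, simulate_agent
from .task import ConfigError, TaskConfig, TrialRecord

CLASS_NAMES = (
    "teacher_dependent",
    "peer_dependent",
    "peer_teacher_dependent",
    "independent",
)

ROI_MAIN = ("put_l", "put_r", "catha_l", "catha_r", "pfc_l", "pfc_r")
ROI_SUB = ("as_stri_l", "as_stri_r", "li_stri_l", "li_stri_r",
           "se_stri_l", "se_stri_r")
ROI_COLUMNS = ROI_MAIN + ROI_SUB

_HI, _LO = 3.3, 1.8

# 4 x 6 parcel-mean profiles (PPM parcels 1-3, TPM parcels 4-6)
DEFAULT_PARCEL_PROFILES = {
    "teacher_dependent": (_LO, _LO, _LO, _HI, _HI, _HI),
    "peer_dependent": (_HI, _HI, _HI, _LO, _LO, _LO),
    "peer_teacher_dependent": (_HI, _HI, _HI, _HI, _HI, _HI),
    "independent": (_LO, _LO, _LO, _LO, _LO, _LO),
}

DEFAULT_ALPHA_MEANS = {
    "teacher_dependent": 0.42,
    "peer_dependent": 0.42,
    "peer_teacher_dependent": 0.55,
    "independent": 0.30,
}

DEFAULT_ROI_OFFSETS = {
    "as_stri_l": {"independent": 0.5},
    "pfc_r": {"peer_teacher_dependent": 0.5},
}


@dataclass(frozen=True)
class ClassParamDist:
    """Natural-space mean/SD for one RL parameter within one class."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), self.lo, self.hi))


def _default_rl_dists() -> dict[str, dict[str, ClassParamDist]]:
    dists: dict[str, dict[str, ClassParamDist]] = {}
    for cname in CLASS_NAMES:
        dists[cname] = {
            "alpha": ClassParamDist(DEFAULT_ALPHA_MEANS[cname], 0.08, 0.03, 0.97),
            "kappa": ClassParamDist(0.40, 0.15, 0.03, 0.97),
            "rho_rew": ClassParamDist(1.6, 0.4, 0.2, np.inf),
            "rho_pun": ClassParamDist(-1.6, 0.4, -np.inf, -0.2),
            "q_init": ClassParamDist(0.0, 0.2),
        }
    return dists


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Class proportions echo the observed four-type membership
    (22.9/26.9/24.2/26.0%); alpha is planted lower in the independent
    class (0.30) than in the peer-and-teacher-dependent class (0.55);
    ROI offsets are +0.5 within-class SDs on the affected regions.
    """

    n_subjects: int = 85
    class_proportions: tuple = (0.23, 0.27, 0.24, 0.26)
    parcel_profiles: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PARCEL_PROFILES.items()}
    )
    item_sd: float = 0.5
    rl_dists: dict = field(default_factory=_default_rl_dists)
    roi_baseline: float = 0.0
    roi_noise_sd: float = 1.0
    roi_offsets: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROI_OFFSETS.items()}
    )
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects")
        if len(self.class_proportions) != len(CLASS_NAMES):
            raise ConfigError("class_proportions must have 4 entries")
        if not np.isclose(sum(self.class_proportions), 1.0):
            raise ConfigError("class proportions must sum to 1")
        if self.item_sd < 0 or self.roi_noise_sd <= 0:
            raise ConfigError("noise SDs must be positive")
        for cname in CLASS_NAMES:
            prof = np.asarray(self.parcel_profiles[cname], dtype=float)
            if prof.shape != (6,):
                raise ConfigError("parcel profiles must be 4 x 6")
            if np.any(prof < 1.0) or np.any(prof > 4.0):
                raise ConfigError("parcel profiles must lie in [1, 4]")
            a = self.rl_dists[cname]["alpha"]
            k = self.rl_dists[cname]["kappa"]
            if not (0 < a.mean < 1 and 0 < k.mean < 1):
                raise ConfigError("alpha and kappa means must be in (0,1)")


def zero_effect_config(base: Optional[CohortConfig] = None) -> CohortConfig:
    """Null-cohort config: all classes share RL and ROI distributions."""
    base = base if base is not None else CohortConfig()
    dists = _default_rl_dists()
    shared = {
        "alpha": ClassParamDist(0.42, 0.08, 0.03, 0.97),
        "kappa": ClassParamDist(0.40, 0.15, 0.03, 0.97),
        "rho_rew": ClassParamDist(1.6, 0.4, 0.2, np.inf),
        "rho_pun": ClassParamDist(-1.6, 0.4, -np.inf, -0.2),
        "q_init": ClassParamDist(0.0, 0.2),
    }
    for cname in CLASS_NAMES:
        dists[cname] = dict(shared)
    return replace(base, rl_dists=dists, roi_offsets={})


@dataclass
class CohortBundle:
    """Everything the pipeline needs, plus the ground truth for scoring."""

    config: CohortConfig
    items: pd.DataFrame                 # subject_id + 15 item columns
    roi: pd.DataFrame                   # subject_id + 12 ROI columns
    sessions: dict                      # subject_id -> list[TrialRecord]
    truth: pd.DataFrame                 # subject_id, true_class, true parameters
    seed: int


# item j of a scale draws its mean from the parcel profile column below
_PPM_ITEM_PARCEL = (0, 0, 0, 1, 1, 1, 2, 2, 2)
_TPM_ITEM_PARCEL = (3, 3, 4, 4, 5, 5)


def _draw_items(profile: np.ndarray, item_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    means = np.concatenate(
        [profile[list(_PPM_ITEM_PARCEL)], profile[list(_TPM_ITEM_PARCEL)]]
    )
    raw = rng.normal(means, item_sd)
    return np.clip(np.rint(raw), 1, 4)


def generate_cohort(config: CohortConfig, seed: int) -> CohortBundle:
    """Draw a complete synthetic cohort under ``config``.

    Per subject: a class label, 15 Likert items (profile + noise,
    round-and-clip to 1..4), RL parameters from the class distribution,
    a 300-trial session simulated by the model agent, and 12 ROI scalar
    covariates with the planted class offsets.
    """
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    z = rng.choice(len(CLASS_NAMES), size=n, p=list(config.class_proportions))
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    item_rows, roi_rows, truth_rows = [], [], []
    sessions: dict[str, list[TrialRecord]] = {}
    for i, sid in enumerate(subject_ids):
        cname = CLASS_NAMES[z[i]]
        profile = np.asarray(config.parcel_profiles[cname], dtype=float)
        items = _draw_items(profile, config.item_sd, rng)
        item_rows.append(
            {"subject_id": sid,
             **{f"ppm_{j + 1}": items[j] for j in range(N_PPM_ITEMS)},
             **{f"tpm_{j + 1}": items[N_PPM_ITEMS + j] for j in range(N_TPM_ITEMS)}}
        )
        dists = config.rl_dists[cname]
        params = SubjectParameters(
            alpha=dists["alpha"].sample(rng),
            kappa=dists["kappa"].sample(rng),
            rho_rew=dists["rho_rew"].sample(rng),
            rho_pun=dists["rho_pun"].sample(rng),
            q_init=dists["q_init"].sample(rng),
        )
        sessions[sid] = simulate_agent(
            params, config.task, rng_seed=int(rng.integers(2**31 - 1))
        )
        roi = {}
        for col in ROI_COLUMNS:
            offset = config.roi_offsets.get(col, {}).get(cname, 0.0)
            roi[col] = config.roi_baseline + offset * config.roi_noise_sd \
                + rng.normal(0.0, config.roi_noise_sd)
        roi_rows.append({"subject_id": sid, **roi})
        truth_rows.append(
            {"subject_id": sid, "true_class": cname,
             "alpha": params.alpha, "kappa": params.kappa,
             "rho_rew": params.rho_rew, "rho_pun": params.rho_pun,
             "q_init": params.q_init}
        )
    return CohortBundle(
        config=config,
        items=pd.DataFrame(item_rows),
        roi=pd.DataFrame(roi_rows),
        sessions=sessions,
        truth=pd.DataFrame(truth_rows),
        seed=seed,
    )


def truth_table(bundle: CohortBundle) -> pd.DataFrame:
    """Per-subject ground truth (class + generating parameters).

    Used only for recovery scoring in tests and reports; the analysis
    pipeline itself never reads it.
    """
    return bundle.truth.copy()


def write_bundle(bundle: CohortBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as the four TSV pipeline inputs + truth table."""
    from .task import write_trials

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "items": out / "items.tsv",
        "trials": out / "trials.tsv",
        "roi": out / "roi.tsv",
        "truth": out / "truth.tsv",
    }
    bundle.items.to_csv(paths["items"], sep="\t", index=False, na_rep="NA")
    write_trials(paths["trials"], bundle.sessions)
    bundle.roi.to_csv(paths["roi"], sep="\t", index=False, na_rep="NA")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def match_classes_to_archetypes(
    solution: LCASolution,
    profiles: Optional[dict] = None,
) -> dict[int, str]:
    """Label fitted latent classes by their parcel-mean archetypes.

    Solves the assignment problem between fitted class means and the
    four archetype profiles (minimum total squared distance), so
    downstream contrasts can be phrased in terms of named motivation
    types regardless of the arbitrary class order the EM produced.
    """
    profiles = profiles if profiles is not None else DEFAULT_PARCEL_PROFILES
    names = list(profiles.keys())
    arch = np.array([profiles[nm] for nm in names], dtype=float)
    cost = ((solution.means[:, None, :] - arch[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {int(r): names[c] for r, c in zip(rows, cols)}
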