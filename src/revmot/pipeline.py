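"""End-to-end pipeline: cohort -> model fit -> LCA -> three-step regression.

Stages run in order with seeds derived deterministically from one master
seed; each stage's outputs are plain tables (TSV/JSON) so intermediate
artifacts are inspectable and replayable.  A stage failure raises
``StageError`` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import hierarchical, latent, qlearning, threestep
from .cohort import (CLASS_NAMES, ROI_MAIN, ROI_SUB, CohortBundle,
                     CohortConfig, generate_cohort,
                     match_classes_to_archetypes)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Master configuration; every stage seed derives from ``seed``."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    em_restarts: int = 5
    em_max_iter: int = 40
    evidence_samples: int = 2000
    literal_double_update: bool = False
    k_range: tuple = (2, 3, 4, 5)
    lca_starts: Optional[int] = None     # None -> fit_lca default policy
    blrt_boot: int = 0                   # 0 disables the BLRT column
    drop_excluded_from_regression: bool = True

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    config: PipelineConfig
    prior: hierarchical.PriorHyper
    fits: pd.DataFrame
    anova_f: float
    anova_p: float
    ic_table: pd.DataFrame
    chosen_k: int
    lca_pi: np.ndarray
    lca_means: np.ndarray
    class_labels: dict
    mean_allocation_probability: float
    blrt_p: Optional[float]
    regression_alpha_roi: pd.DataFrame
    regression_striatal: pd.DataFrame
    n_excluded_low_performance: int
    n_failed_chance_screen: int

    def summary(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_subjects": int(len(self.fits)),
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "chosen_k": int(self.chosen_k),
            "mean_allocation_probability": self.mean_allocation_probability,
            "blrt_p": self.blrt_p,
            "n_excluded_low_performance": self.n_excluded_low_performance,
            "n_failed_chance_screen": self.n_failed_chance_screen,
            "prior_mu": self.prior.mu.tolist(),
            "prior_sigma2": self.prior.sigma2.tolist(),
        }


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {name: int(rng.integers(2**31 - 1))
            for name in ("cohort", "fit", "parcels", "lca", "blrt", "regress")}


def fit_stage(
    sessions: dict,
    config: PipelineConfig,
    seed: int,
) -> tuple[hierarchical.EMResult, pd.DataFrame]:
    """Hierarchical model fit + exclusion screening for one cohort."""
    result = hierarchical.em_loop(
        sessions,
        n_restarts=config.em_restarts,
        max_iter=config.em_max_iter,
        rng_seed=seed,
        evidence_samples=config.evidence_samples,
        literal=config.literal_double_update,
    )
    perf = {sid: qlearning.percent_correct(tr) for sid, tr in sessions.items()}
    hierarchical.apply_exclusions(result.fits, perf)
    frame = hierarchical.fits_to_frame(result.fits)
    frame["percent_correct"] = frame["subject_id"].map(perf)
    return result, frame


def lca_stage(
    items: pd.DataFrame,
    config: PipelineConfig,
    parcel_seed: int,
    lca_seed: int,
    blrt_seed: int,
) -> tuple[latent.ParcelMatrix, pd.DataFrame, latent.LCASolution, Optional[float]]:
    """Parcels, IC model-selection table, chosen solution, optional BLRT."""
    parcels = latent.build_parcels(items, seed=parcel_seed)
    table = latent.ic_table(parcels, config.k_range, seed=lca_seed,
                            n_starts=config.lca_starts)
    chosen_k = int(table.loc[table["bic"].idxmin(), "k"])
    solution = latent.fit_lca(parcels, chosen_k, config.lca_starts, seed=lca_seed)
    blrt_p = None
    if config.blrt_boot:
        blrt_p, _ = latent.blrt(parcels, chosen_k, n_boot=config.blrt_boot,
                                seed=blrt_seed)
    return parcels, table, solution, blrt_p


def regression_stage(
    solution: latent.LCASolution,
    fits: pd.DataFrame,
    roi: pd.DataFrame,
    subject_ids: Sequence[str],
    config: PipelineConfig,
    parcel_profiles: Optional[dict] = None,
) -> tuple[dict, pd.DataFrame, pd.DataFrame, float, float]:
    """Three-step regressions of class on (alpha + ROIs) and striatal subregions.

    Returns (class label map, alpha+ROI table, striatal table, anova F, p).
    Subjects flagged by the exclusion rules are dropped from the
    regressions (but kept in the measurement model).
    """
    w, d = latent.classification_error(solution)
    labels = match_classes_to_archetypes(solution, parcel_profiles)
    label_list = [labels.get(j, f"class{j + 1}") for j in range(solution.k)]

    data = pd.DataFrame({"subject_id": list(subject_ids), "w": w})
    data = data.merge(fits, on="subject_id").merge(roi, on="subject_id")
    if config.drop_excluded_from_regression:
        keep = data["better_than_chance"].astype(bool) & ~data[
            "excluded_low_performance"].astype(bool)
        data = data[keep].reset_index(drop=True)

    # behavioural check: percent correct must not differ systematically by class
    groups = [g["percent_correct"].to_numpy()
              for _, g in data.groupby("w") if len(g) >= 2]
    if len(groups) >= 2:
        anova_f, anova_p = qlearning.group_anova(groups)
    else:
        anova_f, anova_p = np.nan, np.nan

    w_kept = data["w"].to_numpy()
    x_main = data[["alpha", *ROI_MAIN]].to_numpy(dtype=float)
    res_main = threestep.three_step_regression(
        w_kept, d, x_main,
        predictor_names=["alpha", *ROI_MAIN],
        class_labels=label_list,
    )
    x_sub = data[list(ROI_SUB)].to_numpy(dtype=float)
    res_sub = threestep.three_step_regression(
        w_kept, d, x_sub,
        predictor_names=list(ROI_SUB),
        class_labels=label_list,
    )
    return labels, res_main.table(), res_sub.table(), anova_f, anova_p


def run_all(config: PipelineConfig, bundle: Optional[CohortBundle] = None,
            out_dir=None) -> PipelineReport:
    """Execute the full pipeline; optionally persist artifacts to ``out_dir``."""
    seeds = _stage_seeds(config.seed)
    try:
        if bundle is None:
            bundle = generate_cohort(config.cohort, seeds["cohort"])
    except Exception as e:  # pragma: no cover - config errors surface earlier
        raise StageError("cohort", str(e)) from e

    try:
        em_result, fits_frame = fit_stage(bundle.sessions, config, seeds["fit"])
    except Exception as e:
        raise StageError("fit", str(e)) from e

    try:
        parcels, table, solution, blrt_p = lca_stage(
            bundle.items, config, seeds["parcels"], seeds["lca"], seeds["blrt"]
        )
    except Exception as e:
        raise StageError("lca", str(e)) from e

    try:
        labels, tab_main, tab_sub, anova_f, anova_p = regression_stage(
            solution, fits_frame, bundle.roi, parcels.subject_ids, config,
            bundle.config.parcel_profiles,
        )
    except Exception as e:
        raise StageError("regress", str(e)) from e

    report = PipelineReport(
        config=config,
        prior=em_result.prior,
        fits=fits_frame,
        anova_f=anova_f,
        anova_p=anova_p,
        ic_table=table,
        chosen_k=solution.k,
        lca_pi=solution.pi,
        lca_means=solution.means,
        class_labels=labels,
        mean_allocation_probability=float(solution.posterior.max(axis=1).mean()),
        blrt_p=blrt_p,
        regression_alpha_roi=tab_main,
        regression_striatal=tab_sub,
        n_excluded_low_performance=int(fits_frame["excluded_low_performance"].sum()),
        n_failed_chance_screen=int((~fits_frame["better_than_chance"].astype(bool)).sum()),
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: PipelineReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.fits.to_csv(out / "subject_fits.tsv", sep="\t", index=False)
    report.ic_table.to_csv(out / "ic_table.tsv", sep="\t", index=False)
    report.regression_alpha_roi.to_csv(
        out / "regression_alpha_roi.tsv", sep="\t", index=False)
    report.regression_striatal.to_csv(
        out / "regression_striatal.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)


def contrast_value(table: pd.DataFrame, predictor: str,
                   cls: str, reference: str) -> float:
    """Pull one log-odds coefficient out of a Table-2-shaped contrast table."""
    row = table[(table["predictor"] == predictor)
                & (table["class"] == cls)
                & (table["reference"] == reference)]
    if len(row) != 1:
        raise KeyError(f"contrast not found: {predictor} {cls} vs {reference}")
    return float(row["B"].iloc[0])
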