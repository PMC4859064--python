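#!/usr/bin/env python
"""Predict motivation-type membership from learning rate and ROI signals.

Runs the bias-adjusted three-step multinomial regression twice, mirroring
the study design: (1) learning rate alpha + six main ROI covariates,
(2) six striatal-subregion covariates.  Coefficients are reported for
every reference class (log-odds B and odds ratio OR per contrast) and
the key planted contrasts are summarized.  Writes
results/regression_alpha_roi.tsv and results/regression_striatal.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from revmot.cohort import ROI_MAIN, ROI_SUB
from revmot.latent import build_parcels, classification_error, fit_lca
from revmot.pipeline import PipelineConfig, contrast_value, regression_stage

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260104  # parcels/LCA must match 04_latent_classes.py


def main() -> None:
    items = pd.read_csv(ROOT / "cohort" / "items.tsv", sep="\t",
                        dtype={"subject_id": str})
    roi = pd.read_csv(ROOT / "cohort" / "roi.tsv", sep="\t",
                      dtype={"subject_id": str})
    fits = pd.read_csv(ROOT / "subject_fits.tsv", sep="\t",
                       dtype={"subject_id": str})
    with open(ROOT / "lca_solution.json") as fh:
        chosen_k = json.load(fh)["k"]

    parcels = build_parcels(items, seed=SEED)
    sol = fit_lca(parcels, chosen_k, seed=SEED)
    labels, tab_main, tab_sub, anova_f, anova_p = regression_stage(
        sol, fits, roi, parcels.subject_ids, PipelineConfig(seed=SEED))
    tab_main.to_csv(ROOT / "regression_alpha_roi.tsv", sep="\t", index=False)
    tab_sub.to_csv(ROOT / "regression_striatal.tsv", sep="\t", index=False)

    print(f"percent-correct one-way ANOVA across classes: "
          f"F = {anova_f:.2f}, p = {anova_p:.2f}")
    print("key contrasts (standardized predictors, log-odds B / OR):")
    for name, tab, pred, a, b in (
        ("learning rate, independent vs peer-and-teacher-dependent",
         tab_main, "alpha", "independent", "peer_teacher_dependent"),
        ("right PFC, peer-and-teacher-dependent vs independent",
         tab_main, "pfc_r", "peer_teacher_dependent", "independent"),
        ("left associative striatum, independent vs peer-and-teacher-dep.",
         tab_sub, "as_stri_l", "independent", "peer_teacher_dependent"),
        ("left associative striatum, independent vs teacher-dependent",
         tab_sub, "as_stri_l", "independent", "teacher_dependent"),
    ):
        bval = contrast_value(tab, pred, a, b)
        print(f"  {name}: B = {bval:+.2f}, OR = {np.exp(bval):.2f}")
    print(f"wrote {ROOT / 'regression_alpha_roi.tsv'}, "
          f"{ROOT / 'regression_striatal.tsv'}")


if __name__ == "__main__":
    main()
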