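#!/usr/bin/env python
"""Check the reversal-task simulator against its design parameters.

Simulates 200 oracle-policy sessions under the default configuration
(300 trials, 80/20 contingencies, 5-of-6 criterion, 20% hazard) and
tabulates the empirical reward rate given a correct choice, the
empirical reversal hazard given criterion attainment, reversal counts
and payout.  Writes results/task_design.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from revmot.task import OraclePolicy, TaskConfig, session_summary, simulate_session

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260101
N_SESSIONS = 200


def main() -> None:
    cfg = TaskConfig()
    rows = []
    n_correct = n_win = n_crit = n_rev = 0
    for i in range(N_SESSIONS):
        trials = simulate_session(cfg, OraclePolicy(), rng_seed=SEED + i)
        s = session_summary(trials, cfg.win_amount, cfg.loss_amount)
        rows.append({"session": i, "n_reversals": s.n_reversals,
                     "percent_correct": s.percent_correct,
                     "win_rate_given_correct": s.win_rate_given_correct,
                     "hazard_given_criterion": s.hazard_given_criterion,
                     "total_payout_eur": s.total_payout})
        for r in trials:
            if r.correct:
                n_correct += 1
                n_win += r.outcome == "WIN"
            if r.criterion_met:
                n_crit += 1
                n_rev += r.reversal_after
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "task_design.tsv", sep="\t", index=False)
    win = 100 * n_win / n_correct
    haz = 100 * n_rev / n_crit
    print(f"{N_SESSIONS} oracle sessions x {cfg.n_trials} trials")
    print(f"win feedback given correct choice: {win:.2f}% "
          f"(design 80%, n={n_correct})")
    print(f"reversal rate given criterion met: {haz:.2f}% "
          f"(design 20%, n={n_crit})")
    print(f"mean reversals/session: {df.n_reversals.mean():.1f}; "
          f"mean payout: {df.total_payout_eur.mean():.2f} EUR")
    print(f"wrote {OUT / 'task_design.tsv'}")


if __name__ == "__main__":
    main()
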