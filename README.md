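# revmot

Reinforcement-learning behaviour and socio-motivational types: a tested,
reusable pipeline linking a five-parameter Q-learning model of a
probabilistic reversal-learning task to latent classes of motivational
(in-)dependence in adolescent students.

Educational-psychology research distinguishes four motivation types
(MTs) by whether a student's scholastic motivation depends on peers,
teachers, both, or neither.  This package implements the computational
arm of a study asking whether basic reinforcement-learning
characteristics — the individual learning rate and prediction-error
(PE)-related brain signals — predict which type a student belongs to.
Because the underlying human data are not deposited, a synthetic cohort
generator reproduces the study's structure (class proportions, planted
learning-rate and ROI effects) so that every stage of the analysis is
executable and testable end to end.

## The model and the analysis

**Task.** 300 trials, two stimuli; the currently "good" stimulus pays
+10 cents with probability 0.8 and loses otherwise, the other with
inverted probabilities.  After 5 correct choices within the last 6
trials (sliding window since the last reversal), the contingency
reverses with probability 0.2 after every further criterion-satisfying
trial.

**Learning model.** A modified Q-learning rule with five free
parameters per subject.  After feedback R on trial t,

    δ_c = R − Q_c          Q_c ← Q_c + α δ_c
    δ_u = −R − Q_u         Q_u ← Q_u + κ α δ_u

with learning rate α ∈ (0,1), double-update weight κ ∈ (0,1) (the task's
anticorrelated contingencies make updating the unchosen option in the
opposite direction adaptive), free reinforcement magnitudes ρ_rew > 0
and ρ_pun < 0 in place of ±1, and an initial-value offset q_init for one
designated stimulus.  Choices follow a unit-temperature softmax,
p(a) = exp(Q_a) / (exp(Q_a) + exp(Q_b)).  Trial-wise δ_c is exported as
the PE regressor (parametric modulator).

**Fitting.** Hierarchical empirical-prior expectation-maximization: a
group-level Gaussian prior over transformed parameters is alternated
with per-subject MAP estimation (Laplace posterior).  Per-subject model
evidence is approximated by Monte-Carlo integration of the likelihood
over prior samples; subjects whose evidence does not beat the
coin-flip likelihood n·log(½), or whose percent-correct is more than
3 SD below the cohort mean, are flagged for exclusion.

**Latent classes.** The 9 peers-as-positive-motivators and 6
teachers-as-positive-motivators Likert items are randomly parcelled
into 3 + 3 item-mean indicators; a Gaussian latent class model
(class-specific means and variances, EM with multiple restarts) is
selected over K = 2..5 by AIC/BIC and a bootstrap likelihood-ratio
test.

**Three-step regression.** Subjects are assigned to their modal class;
the classification-error matrix D is carried into a bias-adjusted
multinomial logistic regression (Vermunt's ML three-step variant) of
class membership on the learning rate and ROI covariates, so
coefficients are not attenuated by assignment error.  Log-odds B and
odds ratios are reported for every reference class.

## Worked example

The numbered scripts under `analysis/` run the full study on the
synthetic cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_task.py
python analysis/02_generate_cohort.py
python analysis/03_fit_rl_model.py
python analysis/04_latent_classes.py
python analysis/05_three_step_regression.py
```

Output of a complete run (seeds fixed in the scripts):

```
win feedback given correct choice: 79.84% (design 80%, n=60000)
reversal rate given criterion met: 20.42% (design 20%, n=29344)
...
alpha recovery: corr(true, fitted) = 0.801
...
 k  loglik  n_params    aic    bic
 2 -443.03        25 936.07 997.14
 3 -363.61        38 803.22 896.04
 4 -299.49        51 700.98 825.56
 5 -289.35        64 706.71 863.04
selected K = 4; BLRT 4 vs 5: p = 0.980 (LR = 20.27)
mean allocation probability: 1.000
...
  learning rate, independent vs peer-and-teacher-dependent: B = -2.08, OR = 0.12
  right PFC, peer-and-teacher-dependent vs independent: B = +0.42, OR = 1.52
  left associative striatum, independent vs peer-and-teacher-dep.: B = +0.59, OR = 1.81
```

Reading: the simulator hits its design parameters; the hierarchical fit
recovers individual learning rates well; BIC selects the true 4-class
structure and the BLRT finds 5 classes not superior; and the planted
effect directions come back — a lower learning rate (OR < 1) and higher
left associative striatum signal for the independent type, and a higher
right-PFC signal for the peer-and-teacher-dependent type.  Coefficient
magnitudes are on the scale of standardized predictors in this
synthetic cohort and are not comparable to any particular empirical
sample.

The same stages are available programmatically:

```python
from revmot import PipelineConfig, run_all
report = run_all(PipelineConfig(seed=1))
print(report.ic_table)
print(report.regression_alpha_roi.head())
```

## Layout

- `src/revmot/` — library: `task` (simulator), `qlearning` (model),
  `hierarchical` (empirical-prior EM), `latent` (parcels, LCA, BLRT),
  `threestep` (bias-adjusted regression), `cohort` (synthetic data),
  `pipeline` (orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite, including acceptance-grade end-to-end
  property checks.
- `docs/methods.md` — modelling and design notes.
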