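# Methods notes

This note records the modelling assumptions, numerical choices and known
limitations of the pipeline, in the order the stages run.

## Task simulator

One session is `n_trials` (default 300) two-choice trials.  The good
stimulus rewards with `p_reward_good` = 0.80, the other with
`p_reward_bad` = 0.20 (inverse contingencies).  The performance
criterion is 5 correct within the last 6 non-missed trials since the
last reversal, evaluated after every trial; the window is undefined
(criterion false) until 6 such trials have elapsed, so a reversal can
never occur within 6 trials of the previous one.  While the criterion
holds, a reversal is drawn independently with `reversal_hazard` = 0.20
after every trial ("hazard persistence"): the alternative reading — a
single draw armed once per criterion attainment — would make the
marginal reversal rate depend on how long the criterion stays
satisfied; we adopt the per-trial hazard as the cleaner generative
process and verify the empirical conditional rate against 0.20.

Missed trials (optional miss probability, default 0) yield no feedback
and count as neither correct nor incorrect for the criterion window,
since a trial without feedback is not a reinforcement event.  Screen
positions, response times and jitter are not simulated; they have no
consequence for the model.  Payout is ±10 cents per trial with no cap:
a cap cannot be reconstructed consistently from a 300-trial ±10-cent
design, so the summary reports the uncapped total.

## Q-learning model

Five free parameters: α (learning rate), κ (double-update weight),
ρ_rew > 0, ρ_pun < 0 (reinforcement magnitudes replacing ±1) and q_init
(initial value of one designated stimulus; the other starts at 0).
Values are indexed at trial entry; the update is applied after
feedback; the reported PE is the pre-update δ_c = R − Q_c.  The softmax
uses unit temperature exactly — choice stochasticity is absorbed by the
free magnitudes, so no separate inverse temperature is identifiable or
needed.

The unchosen-option update deserves care.  A literal unchosen update of
the form Q_u ← Q_u − κα(R − Q_u) has a repelling fixed point (the value
is pushed *away* from R) and diverges geometrically whenever κα is
large; it cannot be a sensible generative rule.  The default is
therefore the standard stable counterfactual form δ_u = −R − Q_u,
Q_u ← Q_u + κα δ_u, which moves the unchosen value toward the *mirrored*
reinforcement and is the form used throughout the double-update
literature for tasks with anticorrelated contingencies.  The literal
form remains available behind a `literal=True` flag and is unit-tested,
including its unboundedness.  With κ = 0 both modes reduce exactly to
single-update Q-learning.  In counterfactual mode Q-values stay inside
[min(ρ_pun, −ρ_rew), max(ρ_rew, −ρ_pun)] whenever they start there.

The likelihood sums −log p(choice) over non-missed trials; missed
trials contribute neither a likelihood term nor an update.  The inner
loop is numba-compiled, with an analytic forward-sensitivity gradient
(verified against finite differences to ~1e-7) used by the optimizer.

Parameters are fitted on an unconstrained scale: logit for α and κ,
log for ρ_rew, log of the magnitude (negated) for ρ_pun, identity for
q_init.  Constraining ρ_pun negative by construction keeps the
reward/punishment asymmetry identifiable.  Transforms are clipped at
±40 before exponentiation so line-search probes cannot overflow.

## Hierarchical empirical-prior EM

The group prior is Gaussian with diagonal covariance on the transformed
scale — five parameters and cohort sizes below 100 do not support a
stable full covariance.  Initial prior: mean 0, variance 6.25 per
coordinate (SD 2.5, weakly informative on logit/log scales).

E-step: per-subject MAP of log-likelihood + log prior density
(L-BFGS-B; best of `n_restarts` = 5 starts from the prior mean and
prior draws on the first iteration, warm-started with one fresh prior
draw on the second, warm-start only thereafter).  The posterior is
approximated by a Laplace curvature: central finite-difference Hessian
(step 1e-4), symmetrized, eigenvalues floored at 1e-6 when repair is
needed.

M-step: μ_j = mean of MAPs; σ²_j = mean(θ² + posterior variance) − μ_j²,
floored at 1e-4.  Convergence: max |Δμ| < 1e-3 or `max_iter`
(100 in the fitting API; the pipeline uses an iteration budget of 40,
after which hyperparameter movement is far below any quantity of
interest — the monitored evidence lower bound changes by < 0.1 nat per
iteration well before that).  The bound (per-subject log-likelihood at
the MAP + log prior density + Laplace entropy) is tracked per iteration
and is non-decreasing up to optimizer tolerance.

Model evidence per subject is log(1/K Σ exp(loglik(θ_k))) over K prior
draws (default 10 000 in the API, 2 000 in the pipeline) with a
log-sum-exp.  A subject is "better than chance" when the evidence
exceeds n_valid·log ½.  The performance exclusion flags percent-correct
below mean − 3 SD, computed once over the full cohort (not iterated).
Every stochastic step takes a seed derived deterministically from the
master seed.

## Latent class analysis

Parcels: a seeded random partition of the 9 PPM items into 3 parcels of
3 and the 6 TPM items into 3 parcels of 2; a parcel is the mean of its
available items, and a parcel with no available items is missing.
Indicators are treated as continuous Gaussians: parcels are means of
1–4 Likert items, which is the standard justification for a continuous
measurement model; likelihood contributions use observed coordinates
only (ignorable missingness).

The mixture has class-specific means and class-specific diagonal
variances, fitted by EM (variance floor 1e-4; restart policy 50 starts
for K ≤ 4, 100 for K = 5).  Because parcel scores live on a coarse
lattice, unconstrained maximum likelihood admits spurious singular
optima — a class parked on a single lattice point with vanishing
variance.  Restarts ending with any class variance ≤ 1e-3 are therefore
discarded as collapsed, the standard guard against singular solutions
in Gaussian mixtures; without it, model selection on discretized data
is driven by lattice artefacts rather than class structure.

Selection reports AIC and BIC (n_params = (K−1) + 2·K·6) with the BIC
minimum selecting K, plus a parametric-bootstrap likelihood-ratio test:
null data are drawn from the fitted K-class model (complete data; the
observed missingness pattern is not resampled), both models are
refitted with a reduced restart budget, and
p = (1 + #{boot ≥ observed}) / (n_boot + 1).

Step two assigns each subject to the modal class (ties to the lowest
index) and computes D[k, s] = Σ post_ik·1[W_i = s] / Σ post_ik.

## Three-step regression

Step three maximizes Σ_i log Σ_k P(C=k | x_i; B)·D[k, W_i] — the
ML bias-adjusted variant (not BCH weighting).  Predictors are z-scored
by default (flagged in the result).  With D = identity this reduces
exactly to an ordinary multinomial logit, which the tests verify
against statsmodels to 1e-4.  Wald standard errors come from the
numerically differentiated observed information.  Separation is
detected when any coefficient magnitude exceeds 10 (on the standardized
scale that is far outside the plausible range; fully separated fits
stall near that size once the score vanishes); the model is then
refitted with a small ridge penalty (1e-2) and flagged.  Coefficients
are re-expressed against every reference class via
B_{a vs b} = B_{a vs ref} − B_{b vs ref}.

## Synthetic cohort

The generator emulates the study conditions: n = 85 subjects in four
classes with proportions 0.23 / 0.27 / 0.24 / 0.26 (teacher-, peer-,
peer-and-teacher-dependent, independent).  Parcel profiles are 3.3 for
a scale the class depends on and 1.8 otherwise — roughly ±0.75 around
the Likert midpoint, giving the strong class separation implied by
mean allocation probabilities above 0.96.  Items are drawn as profile
mean + N(0, 0.5), rounded and clipped to 1..4 (round-and-clip rather
than a thresholded ordinal model; sufficient for item-mean parcels).

RL parameters are drawn per class in natural space (clipped Gaussians):
α means 0.55 (peer-and-teacher-dependent), 0.30 (independent), 0.42
(both single-source classes), SD 0.08 — the planted direction of the
learning-rate effect; κ ~ N(0.40, 0.15), ρ_rew ~ N(1.6, 0.4),
ρ_pun ~ N(−1.6, 0.4), q_init ~ N(0, 0.2).  Magnitudes around 1.6 give
softmax choice probabilities up to ≈0.96 and clearly identifiable
learning, which is what competent adolescent performance on this task
looks like.  ROI covariates are generated directly as post-GLM scalar
estimates — unit-SD Gaussian noise around 0 with +0.5 SD offsets on the
left associative striatum for the independent class and the right PFC
for the peer-and-teacher-dependent class.  No BOLD time series, HRF or
image-level noise is simulated: the pipeline consumes cluster-averaged
scalars, so image-level realism would add cost without exercising any
additional code path.

What passing tests therefore show: the pipeline recovers class
structure, learning-rate ordering and effect directions from data whose
noise is Gaussian, whose items are conditionally independent given
class, and whose choices truly come from the fitted model family.  Real
questionnaire data have correlated item residuals and real choice data
have drifts, lapses and model misfit; the tests bound implementation
correctness, not robustness to those.

## Problem sizes

Simulation-based checks use: 200 sessions for task design rates;
20-seed replicates for parameter recovery (n = 60 cohorts), LCA
selection (n = 85) and end-to-end effect directions (n = 85); 8
replicates at n_boot = 199 for BLRT null calibration; 40 replicates for
the evidence screen.  These sizes make the Monte-Carlo error small
relative to each criterion's margin while keeping a full run on one
CPU in minutes.

## Known limitations

- The empirical-prior EM uses MAP + Laplace moments, not full posterior
  sampling; heavy-tailed or multimodal subject posteriors are
  summarized by a local Gaussian.
- Absolute regression coefficients depend on predictor scaling and the
  synthetic effect sizes; only signs and orderings are meaningful
  targets.
- The BLRT resamples complete data from the fitted model, so its
  calibration under substantial missingness is untested.
- q_init attaches to a fixed designated stimulus; counterbalancing of
  the designated option across subjects is not modelled.
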