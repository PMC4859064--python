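"""Latent class analysis of socio-motivational questionnaire parcels.

The measurement model is a finite mixture of Gaussians over six parcel
scores (three random parcels of the nine peers-as-positive-motivators
items, three of the six teachers-as-positive-motivators items), with
class-specific means and class-specific diagonal variances, fitted by EM
with multiple seeded restarts.  Model selection uses AIC/BIC and a
parametric bootstrap likelihood-ratio test (BLRT) of K vs K+1 classes.
Missing parcels contribute only their observed coordinates to the
likelihood (ignorable missingness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

N_PPM_ITEMS = 9
N_TPM_ITEMS = 6
N_PARCELS = 6
VAR_FLOOR = 1e-4
# Parcel scores live on a coarse Likert lattice, so unconstrained ML can
# park a class on a single lattice point with vanishing variance — a
# spurious singular maximum.  Restarts that end with any class variance
# this small are treated as collapsed and discarded.
SPURIOUS_VAR = 1e-3


class SchemaError(ValueError):
    pass


class DegenerateSolutionError(RuntimeError):
    pass


@dataclass
class ParcelMatrix:
    """Subjects x 6 parcel scores on the 1-4 Likert scale.

    Columns 0-2 are PPM parcels, 3-5 TPM parcels.  ``assignment`` stores
    the seeded item->parcel partition so the parcelling is reproducible.
    """

    scores: np.ndarray                  # (n, 6), NaN = missing
    subject_ids: list[str]
    assignment: dict[str, list[list[int]]]

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def build_parcels(items: pd.DataFrame, seed: int) -> ParcelMatrix:
    """Randomly parcel 9 PPM + 6 TPM items into 3 + 3 item-mean scores.

    ``items`` must have a subject_id column plus 9 columns named
    ppm_1..ppm_9 and 6 named tpm_1..tpm_6 with values in {1,2,3,4} or
    missing.  The partition is a seeded permutation; a parcel whose
    items are all missing is missing.
    """
    ppm_cols = [f"ppm_{i}" for i in range(1, N_PPM_ITEMS + 1)]
    tpm_cols = [f"tpm_{i}" for i in range(1, N_TPM_ITEMS + 1)]
    missing = [c for c in ["subject_id", *ppm_cols, *tpm_cols] if c not in items.columns]
    if missing:
        raise SchemaError(f"item matrix missing columns: {missing}")
    vals = items[ppm_cols + tpm_cols].to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, [1.0, 2.0, 3.0, 4.0])
    if not ok.all():
        raise SchemaError("item values must be in {1,2,3,4} or missing")

    rng = np.random.default_rng(seed)
    ppm_perm = rng.permutation(N_PPM_ITEMS)
    tpm_perm = rng.permutation(N_TPM_ITEMS)
    ppm_parcels = [sorted(ppm_perm[i::3].tolist()) for i in range(3)]
    tpm_parcels = [sorted(tpm_perm[i::3].tolist()) for i in range(3)]

    n = len(items)
    scores = np.full((n, N_PARCELS), np.nan)
    ppm_vals = vals[:, :N_PPM_ITEMS]
    tpm_vals = vals[:, N_PPM_ITEMS:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for j, idx in enumerate(ppm_parcels):
            scores[:, j] = np.nanmean(ppm_vals[:, idx], axis=1)
        for j, idx in enumerate(tpm_parcels):
            scores[:, 3 + j] = np.nanmean(tpm_vals[:, idx], axis=1)
    return ParcelMatrix(
        scores=scores,
        subject_ids=items["subject_id"].astype(str).tolist(),
        assignment={"ppm": ppm_parcels, "tpm": tpm_parcels},
    )


@dataclass
class LCASolution:
    """Fitted K-class Gaussian measurement model."""

    k: int
    pi: np.ndarray                      # (K,)
    means: np.ndarray                   # (K, 6)
    variances: np.ndarray               # (K, 6)
    posterior: np.ndarray               # (n, K)
    loglik: float
    n: int

    @property
    def n_params(self) -> int:
        return (self.k - 1) + 2 * self.k * self.means.shape[1]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n)


def _log_obs_density(x: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, K) log density over observed coordinates only."""
    n, d = x.shape
    k = means.shape[0]
    obs = ~np.isnan(x)
    xf = np.where(obs, x, 0.0)
    out = np.zeros((n, k))
    for j in range(k):
        resid2 = (xf - means[j]) ** 2
        terms = -0.5 * (np.log(2.0 * np.pi * variances[j]) + resid2 / variances[j])
        out[:, j] = np.where(obs, terms, 0.0).sum(axis=1)
    return out


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int = 300, tol: float = 1e-7,
) -> Optional[LCASolution]:
    n, d = x.shape
    obs = ~np.isnan(x)
    # init: means at perturbed random subjects, shared variance
    idx = rng.choice(n, size=k, replace=False)
    col_mean = np.nanmean(x, axis=0)
    col_var = np.nanvar(x, axis=0) + 1e-2
    means = np.where(obs[idx], x[idx], col_mean) + rng.normal(0, 0.1, size=(k, d))
    variances = np.tile(col_var, (k, 1))
    pi = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    xf = np.where(obs, x, 0.0)
    for _ in range(max_iter):
        logdens = _log_obs_density(x, means, variances) + np.log(pi)
        m = logdens.max(axis=1, keepdims=True)
        w = np.exp(logdens - m)
        tot = w.sum(axis=1, keepdims=True)
        ll = float((m.ravel() + np.log(tot.ravel())).sum())
        post = w / tot
        nk = post.sum(axis=0)
        if np.any(nk < 1e-8):
            return None  # empty-class collapse; caller restarts
        pi = nk / n
        # per-dimension weighted moments over observed entries
        for j in range(k):
            wj = post[:, j][:, None] * obs
            denom = wj.sum(axis=0)
            if np.any(denom < 1e-8):
                return None
            mu = (post[:, j][:, None] * xf).sum(axis=0) / denom
            var = (wj * (np.where(obs, x, mu[None]) - mu) ** 2).sum(axis=0) / denom
            means[j] = mu
            variances[j] = np.maximum(var, VAR_FLOOR)
        if ll - prev_ll < tol * max(1.0, abs(ll)) and ll >= prev_ll - 1e-9:
            prev_ll = ll
            break
        prev_ll = ll
    if np.any(variances <= SPURIOUS_VAR):
        return None  # singular lattice-point solution; caller restarts
    logdens = _log_obs_density(x, means, variances) + np.log(pi)
    m = logdens.max(axis=1, keepdims=True)
    w = np.exp(logdens - m)
    tot = w.sum(axis=1, keepdims=True)
    loglik = float((m.ravel() + np.log(tot.ravel())).sum())
    post = w / tot
    order = np.argsort(-pi)  # canonical order: descending weight
    return LCASolution(
        k=k, pi=pi[order], means=means[order], variances=variances[order],
        posterior=post[:, order], loglik=loglik, n=n,
    )


def fit_lca(
    parcels: ParcelMatrix | np.ndarray,
    k: int,
    n_starts: Optional[int] = None,
    seed: int = 0,
) -> LCASolution:
    """Fit the K-class mixture; best of ``n_starts`` seeded EM restarts.

    Default restart policy: 50 starts for K <= 4, 100 for K = 5+.
    """
    x = parcels.scores if isinstance(parcels, ParcelMatrix) else np.asarray(parcels, float)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} subjects for k={k}")
    if k == 1:
        obs = ~np.isnan(x)
        mu = np.nanmean(x, axis=0)
        var = np.maximum(np.nanvar(x, axis=0), VAR_FLOOR)
        ll = float(np.nansum(
            np.where(obs, -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var), 0.0)
        ))
        return LCASolution(
            k=1, pi=np.array([1.0]), means=mu[None], variances=var[None],
            posterior=np.ones((n, 1)), loglik=ll, n=n,
        )
    if n_starts is None:
        n_starts = 50 if k <= 4 else 100
    rng = np.random.default_rng(seed)
    best: Optional[LCASolution] = None
    failures = 0
    for _ in range(n_starts):
        sol = _em_once(x, k, rng)
        if sol is None:
            failures += 1
            continue
        if best is None or sol.loglik > best.loglik:
            best = sol
    if best is None:
        raise DegenerateSolutionError(
            f"all {n_starts} EM restarts collapsed for k={k}"
        )
    return best


def sample_from_solution(
    solution: LCASolution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a complete parcel matrix from the fitted mixture."""
    z = rng.choice(solution.k, size=n, p=solution.pi)
    x = rng.normal(solution.means[z], np.sqrt(solution.variances[z]))
    return x


def blrt(
    parcels: ParcelMatrix | np.ndarray,
    k: int,
    n_boot: int = 199,
    seed: int = 0,
    n_starts_obs: Optional[int] = None,
    n_starts_boot: int = 10,
    max_failure_frac: float = 0.2,
) -> tuple[float, float]:
    """Bootstrap likelihood-ratio test of K vs K+1 classes.

    Returns (p_value, observed LR).  The LR statistic is
    -2(loglik_K - loglik_{K+1}); null datasets are drawn from the fitted
    K-class model and refitted at both K and K+1 with seeded restarts;
    p = (1 + #{boot >= observed}) / (n_boot + 1).
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    x = parcels.scores if isinstance(parcels, ParcelMatrix) else np.asarray(parcels, float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    fit_k = fit_lca(x, k, n_starts_obs, seed=int(rng.integers(2**31 - 1)))
    fit_k1 = fit_lca(x, k + 1, n_starts_obs, seed=int(rng.integers(2**31 - 1)))
    observed = -2.0 * (fit_k.loglik - fit_k1.loglik)
    stats = []
    failures = 0
    while len(stats) < n_boot:
        if failures > max_failure_frac * n_boot + 5:
            raise DegenerateSolutionError("too many non-convergent bootstrap fits")
        xb = sample_from_solution(fit_k, n, rng)
        try:
            bk = fit_lca(xb, k, n_starts_boot, seed=int(rng.integers(2**31 - 1)))
            bk1 = fit_lca(xb, k + 1, n_starts_boot, seed=int(rng.integers(2**31 - 1)))
        except DegenerateSolutionError:
            failures += 1
            continue
        stats.append(-2.0 * (bk.loglik - bk1.loglik))
    stats = np.array(stats)
    p = (1.0 + float(np.sum(stats >= observed))) / (n_boot + 1.0)
    return p, observed


def ic_table(
    parcels: ParcelMatrix | np.ndarray,
    k_range: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
    n_starts: Optional[int] = None,
) -> pd.DataFrame:
    """AIC/BIC model-selection table over a range of class counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        sol = fit_lca(parcels, k, n_starts, seed=int(rng.integers(2**31 - 1)))
        rows.append({"k": k, "loglik": sol.loglik, "n_params": sol.n_params,
                     "aic": sol.aic, "bic": sol.bic})
    return pd.DataFrame(rows)


def classification_error(solution: LCASolution) -> tuple[np.ndarray, np.ndarray]:
    """Modal assignments W and the classification-error matrix D.

    W_i = argmax_k posterior_ik (ties to the lowest class index);
    D[k, s] = sum_i post_ik * 1[W_i = s] / sum_i post_ik, i.e. the
    probability of being assigned to class s given true class k.
    """
    post = solution.posterior
    w = np.argmax(post, axis=1)  # argmax takes the first (lowest) index on ties
    k = solution.k
    d = np.zeros((k, k))
    for s in range(k):
        d[:, s] = post[w == s].sum(axis=0)
    d /= post.sum(axis=0)[:, None]
    return w, d
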