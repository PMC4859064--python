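"""Bias-adjusted three-step latent-class regression (Vermunt's ML variant).

Step one fits the latent class measurement model (``latent.fit_lca``);
step two assigns subjects to their modal class and quantifies the
assignment error matrix D (``latent.classification_error``); step three
regresses the assigned class on covariates by maximum likelihood,
treating the modal assignment as an indicator of the true class observed
with known error probabilities D, so the regression coefficients are not
attenuated by classification error:

    L(B) = sum_i log sum_k P(C=k | x_i; B) * D[k, W_i]

With D = identity this reduces exactly to an ordinary multinomial logit
on (W, X).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

log = logging.getLogger(__name__)

SEPARATION_NORM = 10.0
RIDGE_PENALTY = 1e-2


@dataclass
class ThreeStepResult:
    """Coefficients of the bias-adjusted multinomial logit.

    ``coef`` has shape (K, p+1) with the internal reference class fixed
    at zero (row 0); column 0 is the intercept.  ``cov`` is the Wald
    covariance of the free coefficients (flattened rows 1..K-1).
    """

    coef: np.ndarray
    cov: Optional[np.ndarray]
    predictor_names: list[str]
    class_labels: list[str]
    loglik: float
    standardized: bool
    ridge_applied: bool
    d_matrix: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray

    @property
    def k(self) -> int:
        return self.coef.shape[0]

    def contrast(self, a: int, b: int) -> np.ndarray:
        """Log-odds coefficients for class a vs class b (a relative to b)."""
        return self.coef[a] - self.coef[b]

    def contrast_se(self, a: int, b: int) -> np.ndarray:
        """Wald standard errors of the a-vs-b contrast."""
        p1 = self.coef.shape[1]
        if self.cov is None:
            return np.full(p1, np.nan)
        se = np.empty(p1)
        for j in range(p1):
            g = np.zeros((self.k - 1) * p1)
            if a > 0:
                g[(a - 1) * p1 + j] = 1.0
            if b > 0:
                g[(b - 1) * p1 + j] -= 1.0
            se[j] = np.sqrt(g @ self.cov @ g)
        return se

    def table(self) -> pd.DataFrame:
        """All pairwise contrasts, each class as reference in turn.

        One row per (reference, class, predictor) with the log-odds
        coefficient B, the odds ratio exp(B) and its Wald SE.
        """
        rows = []
        names = ["intercept"] + list(self.predictor_names)
        for ref in range(self.k):
            for a in range(self.k):
                if a == ref:
                    continue
                b = self.contrast(a, ref)
                se = self.contrast_se(a, ref)
                for j, nm in enumerate(names):
                    rows.append(
                        {
                            "reference": self.class_labels[ref],
                            "class": self.class_labels[a],
                            "predictor": nm,
                            "B": b[j],
                            "OR": float(np.exp(b[j])),
                            "se": se[j],
                        }
                    )
        return pd.DataFrame(rows)


def _class_probs(x1: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """(n, K) softmax probabilities; coef rows are per-class, row0 = 0."""
    logits = x1 @ coef.T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _negloglik(flat: np.ndarray, x1: np.ndarray, d_w: np.ndarray,
               k: int, ridge: float) -> float:
    p1 = x1.shape[1]
    coef = np.zeros((k, p1))
    coef[1:] = flat.reshape(k - 1, p1)
    probs = _class_probs(x1, coef)
    lik = (probs * d_w).sum(axis=1)
    pen = ridge * float(np.sum(flat**2))
    return -float(np.sum(np.log(np.maximum(lik, 1e-300)))) + pen


def _fd_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        h[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return 0.5 * (h + h.T)


def three_step_regression(
    w: np.ndarray,
    d: np.ndarray,
    x: np.ndarray,
    predictor_names: Optional[Sequence[str]] = None,
    class_labels: Optional[Sequence[str]] = None,
    standardize: bool = True,
    compute_se: bool = True,
) -> ThreeStepResult:
    """Step-three regression of assigned class on covariates.

    Parameters
    ----------
    w : (n,) modal class assignments in 0..K-1.
    d : (K, K) classification-error matrix, rows summing to 1.
    x : (n, p) predictor matrix (standardized internally by default).
    """
    w = np.asarray(w, dtype=int)
    d = np.asarray(d, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != w.shape[0]:
        raise ValueError("w and x disagree on the number of subjects")
    k = d.shape[0]
    if d.shape != (k, k):
        raise ValueError("D must be square")
    if not np.allclose(d.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of D must sum to 1")
    if np.any(np.isnan(x)):
        raise ValueError("predictor matrix contains missing values")
    n, p = x.shape
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    if class_labels is None:
        class_labels = [f"class{j + 1}" for j in range(k)]

    x_mean = x.mean(axis=0)
    x_scale = x.std(axis=0, ddof=0)
    if standardize:
        safe = np.where(x_scale > 0, x_scale, 1.0)
        xs = (x - x_mean) / safe
    else:
        xs = x
    x1 = np.column_stack([np.ones(n), xs])
    d_w = d[:, w].T  # (n, K): D[k, W_i] as column k of row i

    def fit(ridge: float):
        flat0 = np.zeros((k - 1) * (p + 1))
        res = minimize(
            _negloglik, flat0, args=(x1, d_w, k, ridge),
            method="BFGS", options={"maxiter": 1000, "gtol": 1e-7},
        )
        return res

    ridge_applied = False
    res = fit(0.0)
    if not np.all(np.isfinite(res.x)) or np.max(np.abs(res.x)) > SEPARATION_NORM:
        log.warning(
            "separation detected (|B| up to %.1f); refitting with ridge %.3g",
            float(np.max(np.abs(res.x))), RIDGE_PENALTY,
        )
        res = fit(RIDGE_PENALTY)
        ridge_applied = True

    coef = np.zeros((k, p + 1))
    coef[1:] = res.x.reshape(k - 1, p + 1)

    cov = None
    if compute_se:
        ridge = RIDGE_PENALTY if ridge_applied else 0.0
        h = _fd_hessian(lambda f_: _negloglik(f_, x1, d_w, k, ridge), res.x)
        try:
            cov = np.linalg.inv(h)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(h)

    return ThreeStepResult(
        coef=coef,
        cov=cov,
        predictor_names=list(predictor_names),
        class_labels=list(class_labels),
        loglik=-_negloglik(res.x, x1, d_w, k,
                           RIDGE_PENALTY if ridge_applied else 0.0),
        standardized=standardize,
        ridge_applied=ridge_applied,
        d_matrix=d,
        x_mean=x_mean,
        x_scale=x_scale,
    )
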