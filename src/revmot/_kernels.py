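"""Numba-compiled inner loops for the Q-learning likelihood.

Trials are encoded as integer arrays: ``choices`` holds 0 (stimulus A),
1 (stimulus B) or -1 (missed); ``outcomes`` holds +1 (win), -1 (loss) or
0 (no feedback).  Missed trials contribute no likelihood term and no
value update.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _log_sigmoid(x):
    # log(1/(1+exp(-x))), overflow-safe
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True)
def nll_kernel(choices, outcomes, alpha, kappa, rho_rew, rho_pun,
               q_init, designated, literal, deltas):
    """Negative log-likelihood; fills ``deltas`` with chosen-option PEs.

    ``designated`` is the index (0/1) of the stimulus carrying the
    initial-value offset.  ``literal`` selects the printed unchosen
    update Q_u -= kappa*alpha*(R - Q_u) instead of the stable
    counterfactual form Q_u += kappa*alpha*(-R - Q_u).
    """
    q = np.zeros(2)
    q[designated] = q_init
    nll = 0.0
    for i in range(choices.shape[0]):
        c = choices[i]
        deltas[i] = np.nan
        if c < 0:
            continue
        d = q[0] - q[1]
        if c == 0:
            nll -= _log_sigmoid(d)
        else:
            nll -= _log_sigmoid(-d)
        o = outcomes[i]
        if o == 0:
            continue
        r = rho_rew if o > 0 else rho_pun
        u = 1 - c
        delta_c = r - q[c]
        deltas[i] = delta_c
        q[c] = q[c] + alpha * delta_c
        if literal:
            q[u] = q[u] - kappa * alpha * (r - q[u])
        else:
            q[u] = q[u] + kappa * alpha * (-r - q[u])
    return nll


@njit(cache=True)
def nll_grad_kernel(choices, outcomes, alpha, kappa, rho_rew, rho_pun,
                    q_init, designated, literal):
    """NLL and its gradient w.r.t. the five natural parameters.

    Forward sensitivity: dq (2 x 5) tracks the derivative of each
    Q-value in the order (alpha, kappa, rho_rew, rho_pun, q_init).
    """
    q = np.zeros(2)
    dq = np.zeros((2, 5))
    q[designated] = q_init
    dq[designated, 4] = 1.0
    nll = 0.0
    grad = np.zeros(5)
    for i in range(choices.shape[0]):
        c = choices[i]
        if c < 0:
            continue
        d = q[0] - q[1]
        # p(A) = sigmoid(d); -dlogp(chosen)/dd
        if d >= 0.0:
            p_a = 1.0 / (1.0 + np.exp(-d))
        else:
            e = np.exp(d)
            p_a = e / (1.0 + e)
        if c == 0:
            nll -= _log_sigmoid(d)
            coef = -(1.0 - p_a)
        else:
            nll -= _log_sigmoid(-d)
            coef = p_a
        for j in range(5):
            grad[j] += coef * (dq[0, j] - dq[1, j])
        o = outcomes[i]
        if o == 0:
            continue
        if o > 0:
            r = rho_rew
            dr_rew, dr_pun = 1.0, 0.0
        else:
            r = rho_pun
            dr_rew, dr_pun = 0.0, 1.0
        u = 1 - c
        delta_c = r - q[c]
        # chosen update: q_c <- q_c + alpha*(r - q_c)
        for j in range(5):
            dr_j = dr_rew if j == 2 else (dr_pun if j == 3 else 0.0)
            da_j = 1.0 if j == 0 else 0.0
            dq[c, j] = dq[c, j] + da_j * delta_c + alpha * (dr_j - dq[c, j])
        q[c] = q[c] + alpha * delta_c
        if literal:
            # q_u <- q_u - kappa*alpha*(r - q_u)
            delta_u = r - q[u]
            for j in range(5):
                dr_j = dr_rew if j == 2 else (dr_pun if j == 3 else 0.0)
                da_j = 1.0 if j == 0 else 0.0
                dk_j = 1.0 if j == 1 else 0.0
                dq[u, j] = dq[u, j] - (dk_j * alpha + kappa * da_j) * delta_u \
                    - kappa * alpha * (dr_j - dq[u, j])
            q[u] = q[u] - kappa * alpha * delta_u
        else:
            # q_u <- q_u + kappa*alpha*(-r - q_u)
            delta_u = -r - q[u]
            for j in range(5):
                dr_j = dr_rew if j == 2 else (dr_pun if j == 3 else 0.0)
                da_j = 1.0 if j == 0 else 0.0
                dk_j = 1.0 if j == 1 else 0.0
                dq[u, j] = dq[u, j] + (dk_j * alpha + kappa * da_j) * delta_u \
                    + kappa * alpha * (-dr_j - dq[u, j])
            q[u] = q[u] + kappa * alpha * delta_u
    return nll, grad


@njit(cache=True)
def nll_batch(choices, outcomes, thetas_nat, designated, literal):
    """NLL for many parameter vectors on one session (prior sampling)."""
    out = np.empty(thetas_nat.shape[0])
    scratch = np.empty(choices.shape[0])
    for k in range(thetas_nat.shape[0]):
        out[k] = nll_kernel(
            choices, outcomes,
            thetas_nat[k, 0], thetas_nat[k, 1], thetas_nat[k, 2],
            thetas_nat[k, 3], thetas_nat[k, 4],
            designated, literal, scratch,
        )
    return out
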