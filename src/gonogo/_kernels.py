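"""Compiled inner loops for trial-sequential likelihood evaluation.

Hierarchical fitting and integrated-likelihood sampling call the session
likelihood tens of thousands of times, so the per-trial recursions for
both model families live here as numba kernels operating on the dense
integer arrays produced by ``Session.to_arrays``.  The public modules
wrap these with parameter handling and validation; small hand-checkable
pieces (weights, choice rule, single updates) are also exposed in pure
Python there so tests can cross-check the kernels trial by trial.

Action coding: go=1, nogo=0, missing=-1.  Missing trials contribute
nothing to the likelihood and trigger no update (no action was emitted,
so no outcome was delivered to learn from).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Pavlovian-bias kinds for the RL kernel
PAV_NONE, PAV_VALUE, PAV_CONSTANT = 0, 1, 2


@njit(cache=False)
def rl_loglik_core(
    ctx,
    action,
    outcome,
    is_win,
    rho_win,
    rho_loss,
    eps,
    xi,
    b,
    pav_weight,
    delta,
    pav_kind,
    p_go_out,
):
    """Sequential log-likelihood of one session under a Rescorla-Wagner variant.

    Model variants are expressed through the arguments: single-sensitivity
    models pass rho_loss == rho_win, bias-free models pass b == 0, the
    noise-free model passes xi == 1, decay-free models pass delta == 0.
    ``pav_kind`` selects no Pavlovian term, the value-weighted term
    (pav_weight * V) or the latched constant term (pav_weight * sgnV).
    """
    n = ctx.shape[0]
    Q = np.zeros((4, 2))  # context x (nogo=0, go=1)
    V = np.zeros(4)
    sgnV = np.zeros(4)
    loglik = 0.0
    for i in range(n):
        s = ctx[i]
        w_go = Q[s, 1] + b
        if pav_kind == PAV_VALUE:
            w_go += pav_weight * V[s]
        elif pav_kind == PAV_CONSTANT:
            w_go += pav_weight * sgnV[s]
        w_nogo = Q[s, 0]
        d = w_go - w_nogo
        p_go = xi / (1.0 + np.exp(-d)) + (1.0 - xi) / 2.0
        p_go_out[i] = p_go
        a = action[i]
        if a < 0:
            continue
        if a == 1:
            loglik += np.log(p_go)
        else:
            loglik += np.log(1.0 - p_go)
        r = float(outcome[i])
        rho = rho_win if is_win[s] == 1 else rho_loss
        Q[s, a] = Q[s, a] + eps * (rho * r - Q[s, a])
        V[s] = V[s] + eps * (rho * r - V[s])
        if sgnV[s] == 0.0 and r != 0.0:
            sgnV[s] = 1.0 if r > 0.0 else -1.0
        if delta > 0.0:
            shrink = 1.0 - delta
            for ss in range(4):
                for aa in range(2):
                    if not (ss == s and aa == a):
                        Q[ss, aa] *= shrink
    return loglik


@njit(cache=False)
def precision_fixed_point(q_go, q_nogo, alpha, tol, max_iter):
    """Iterate policy posterior and precision to convergence (beta = 1).

    q_* are the belief-weighted policy qualities (<= 0).  Returns
    (gamma, pi_go, n_iter); gamma lies in (0, alpha] since the
    denominator 1 - pi'q >= 1.
    """
    gamma = alpha
    pi_go = 0.5
    for it in range(max_iter):
        m = max(gamma * q_go, gamma * q_nogo)
        e_go = np.exp(gamma * q_go - m)
        e_nogo = np.exp(gamma * q_nogo - m)
        pi_go = e_go / (e_go + e_nogo)
        qbar = pi_go * q_go + (1.0 - pi_go) * q_nogo
        gamma_new = alpha / (1.0 - qbar)
        if abs(gamma_new - gamma) < tol:
            return gamma_new, pi_go, it + 1
        gamma = gamma_new
    return gamma, pi_go, max_iter


@njit(cache=False)
def ai_loglik_core(
    ctx,
    n_gap,
    first,
    action,
    outcome,
    D0,
    Qmat,
    lik,
    f,
    alpha,
    tol,
    max_iter,
    p_go_out,
    gamma_out,
    belief_out,
):
    """Sequential log-likelihood of one session under the active-inference agent.

    Per trial: leaky-memory mixing of the stored context posterior toward
    the Pavlovian prior D0, fixed-point inference of policy precision,
    state-marginalized choice probability, then Bayes update of the
    stored posterior from the observed action/outcome.

    D0: (4,) prior over contexts; Qmat: (2, 4) KL policy quality
    (rows nogo, go) for each candidate context; lik: (4, 2, 3) outcome
    likelihood p(o | ctxt, a) with o indexed as outcome + 1.
    Returns -inf if an observation has zero likelihood under every context.
    """
    n = ctx.shape[0]
    stored = np.zeros((4, 4))
    loglik = 0.0
    for i in range(n):
        k = ctx[i]
        if first[i]:
            D_t = D0.copy()
        else:
            g = n_gap[i]
            w_keep = 1.0 - f**g
            w_prior = 1.0 - (1.0 - f) ** g
            D_t = stored[k] * w_keep + D0 * w_prior
            D_t = D_t / D_t.sum()
        # belief-weighted policy qualities
        q_go = 0.0
        q_nogo = 0.0
        for s in range(4):
            q_go += Qmat[1, s] * D_t[s]
            q_nogo += Qmat[0, s] * D_t[s]
        gamma, _, _ = precision_fixed_point(q_go, q_nogo, alpha, tol, max_iter)
        # choice probability marginalized over the per-state policy posterior
        p_go = 0.0
        for s in range(4):
            m = max(gamma * Qmat[1, s], gamma * Qmat[0, s])
            e_go = np.exp(gamma * Qmat[1, s] - m)
            e_nogo = np.exp(gamma * Qmat[0, s] - m)
            p_go += D_t[s] * e_go / (e_go + e_nogo)
        p_go_out[i] = p_go
        gamma_out[i] = gamma
        for s in range(4):
            belief_out[i, s] = D_t[s]
        a = action[i]
        if a < 0:
            # no response: belief persists, simply decayed
            stored[k] = D_t
            continue
        if a == 1:
            loglik += np.log(p_go)
        else:
            loglik += np.log(1.0 - p_go)
        o = outcome[i] + 1
        tot = 0.0
        for s in range(4):
            stored[k, s] = D_t[s] * lik[s, a, o]
            tot += stored[k, s]
        if tot <= 0.0:
            return -np.inf
        for s in range(4):
            stored[k, s] /= tot
    return loglik
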