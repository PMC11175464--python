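"""Compiled inner loops for the model likelihoods.

The trial recursion is inherently sequential, so the hot paths (used by the
MAP optimizer thousands of times per fit) are numba-compiled scalar loops.
``trace_two_policy`` duplicates the recursion of ``nll_two_policy`` while
also recording every latent; the two paths are held together by the
generative/likelihood consistency tests.
"""

import numpy as np
from numba import njit

CLAMP = 700.0


@njit(cache=True)
def _sigmoid(x):
    if x > CLAMP:
        return 1.0
    if x < -CLAMP:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _logit(p):
    if p <= 0.0:
        return -CLAMP
    if p >= 1.0:
        return CLAMP
    return np.log(p / (1.0 - p))


@njit(cache=True)
def _softmax2_p0(u0, u1):
    m = u0 if u0 > u1 else u1
    e0 = np.exp(u0 - m)
    e1 = np.exp(u1 - m)
    return e0 / (e0 + e1)


@njit(cache=True)
def nll_two_policy(a1, a2, r1, r2, newblock,
                   alpha, beta, rho, epsilon,
                   dynamic_weight, fixed_weight, cf_mode, decay):
    """Negative log likelihood of the two-policy arbitration model.

    a1, a2: 0-based chosen actions per trial/decision; r1, r2: centered
    rewards delivered by decision 1 and 2; newblock: 1 where a block starts.
    dynamic_weight selects the surprise-minimization arbitration; otherwise
    the weight is fixed at ``fixed_weight``.  cf_mode: 0 counterfactual,
    1 learning-rate decay, 2 free decay (uses ``decay``).
    """
    T = a1.shape[0]
    Vc = np.zeros((2, 2))
    Vi = np.zeros((2, 2))
    omega = 0.0
    prev0 = -1
    prev1 = -1
    nll = 0.0
    for t in range(T):
        if newblock[t] == 1:
            Vc[:, :] = 0.0
            Vi[:, :] = 0.0
            omega = 0.0
            prev0 = -1
            prev1 = -1
        if dynamic_weight:
            w = _sigmoid(omega)
        else:
            w = fixed_weight
        for d in range(2):
            a = a1[t] if d == 0 else a2[t]
            prev = prev0 if d == 0 else prev1
            u0 = beta * (w * Vc[d, 0] + (1.0 - w) * Vi[d, 0])
            u1 = beta * (w * Vc[d, 1] + (1.0 - w) * Vi[d, 1])
            if prev == 0:
                u0 += rho
            elif prev == 1:
                u1 += rho
            p0 = _softmax2_p0(u0, u1)
            p = p0 if a == 0 else 1.0 - p0
            if p < 1e-300:
                p = 1e-300
            nll -= np.log(p)
        # prediction errors from pre-update values
        dc0 = r1[t] - Vc[0, a1[t]]
        dc1 = r2[t] - Vc[1, a2[t]]
        di0 = r2[t] - Vi[0, a1[t]]
        di1 = r1[t] - Vi[1, a2[t]]
        # value updates (chosen; unchosen per counterfactual mode)
        for d in range(2):
            a = a1[t] if d == 0 else a2[t]
            dc = dc0 if d == 0 else dc1
            di = di0 if d == 0 else di1
            Vc[d, a] += alpha * dc
            Vi[d, a] += alpha * di
            if cf_mode == 0:
                Vc[d, 1 - a] -= alpha * dc
                Vi[d, 1 - a] -= alpha * di
            elif cf_mode == 1:
                Vc[d, 1 - a] *= (1.0 - alpha)
                Vi[d, 1 - a] *= (1.0 - alpha)
            else:
                Vc[d, 1 - a] *= (1.0 - decay)
                Vi[d, 1 - a] *= (1.0 - decay)
        if dynamic_weight:
            ev_o1 = abs(di1) - abs(dc0)
            ev_o2 = abs(di0) - abs(dc1)
            omega += epsilon * (ev_o1 + ev_o2)
        prev0 = a1[t]
        prev1 = a2[t]
    return nll


@njit(cache=True)
def trace_two_policy(a1, a2, r1, r2, newblock,
                     alpha, beta, rho, epsilon,
                     dynamic_weight, fixed_weight, cf_mode, decay,
                     Vc_out, Vi_out, dc_out, di_out, sc_out, si_out,
                     ev_out, omega_out, weight_out, p1_out, pch_out):
    """Same recursion as ``nll_two_policy`` with all latents recorded.

    Output arrays (preallocated by the caller): Vc_out/Vi_out (T,2,2) are
    the values *used at choice time* (pre-update); dc/di (T,2) prediction
    errors; sc/si (T,2) surprise; ev (T,2) evidence per outcome
    [delta(o1), delta(o2)]; omega/weight (T,) at choice time; p1 (T,2)
    probability of action index 0; pch (T,2) probability of the chosen
    action.  Returns the NLL.
    """
    T = a1.shape[0]
    Vc = np.zeros((2, 2))
    Vi = np.zeros((2, 2))
    omega = 0.0
    prev0 = -1
    prev1 = -1
    nll = 0.0
    for t in range(T):
        if newblock[t] == 1:
            Vc[:, :] = 0.0
            Vi[:, :] = 0.0
            omega = 0.0
            prev0 = -1
            prev1 = -1
        if dynamic_weight:
            w = _sigmoid(omega)
            omega_out[t] = omega
        else:
            w = fixed_weight
            omega_out[t] = _logit(fixed_weight)
        weight_out[t] = w
        for d in range(2):
            for a in range(2):
                Vc_out[t, d, a] = Vc[d, a]
                Vi_out[t, d, a] = Vi[d, a]
        for d in range(2):
            a = a1[t] if d == 0 else a2[t]
            prev = prev0 if d == 0 else prev1
            u0 = beta * (w * Vc[d, 0] + (1.0 - w) * Vi[d, 0])
            u1 = beta * (w * Vc[d, 1] + (1.0 - w) * Vi[d, 1])
            if prev == 0:
                u0 += rho
            elif prev == 1:
                u1 += rho
            p0 = _softmax2_p0(u0, u1)
            p1_out[t, d] = p0
            p = p0 if a == 0 else 1.0 - p0
            if p < 1e-300:
                p = 1e-300
            pch_out[t, d] = p
            nll -= np.log(p)
        dc0 = r1[t] - Vc[0, a1[t]]
        dc1 = r2[t] - Vc[1, a2[t]]
        di0 = r2[t] - Vi[0, a1[t]]
        di1 = r1[t] - Vi[1, a2[t]]
        dc_out[t, 0] = dc0
        dc_out[t, 1] = dc1
        di_out[t, 0] = di0
        di_out[t, 1] = di1
        sc_out[t, 0] = abs(dc0)
        sc_out[t, 1] = abs(dc1)
        si_out[t, 0] = abs(di0)
        si_out[t, 1] = abs(di1)
        ev_out[t, 0] = abs(di1) - abs(dc0)
        ev_out[t, 1] = abs(di0) - abs(dc1)
        for d in range(2):
            a = a1[t] if d == 0 else a2[t]
            dc = dc0 if d == 0 else dc1
            di = di0 if d == 0 else di1
            Vc[d, a] += alpha * dc
            Vi[d, a] += alpha * di
            if cf_mode == 0:
                Vc[d, 1 - a] -= alpha * dc
                Vi[d, 1 - a] -= alpha * di
            elif cf_mode == 1:
                Vc[d, 1 - a] *= (1.0 - alpha)
                Vi[d, 1 - a] *= (1.0 - alpha)
            else:
                Vc[d, 1 - a] *= (1.0 - decay)
                Vi[d, 1 - a] *= (1.0 - decay)
        if dynamic_weight:
            omega += epsilon * (ev_out[t, 0] + ev_out[t, 1])
        prev0 = a1[t]
        prev1 = a2[t]
    return nll


@njit(cache=True)
def nll_joint(aj, rsum, newblock, alpha, beta, rho):
    """NLL of the joint-action model: one 4-way softmax choice per trial,
    a scalar prediction error against the summed centered outcomes, no
    counterfactual updating."""
    T = aj.shape[0]
    V = np.zeros(4)
    prev = -1
    nll = 0.0
    u = np.empty(4)
    for t in range(T):
        if newblock[t] == 1:
            V[:] = 0.0
            prev = -1
        m = -1e308
        for j in range(4):
            u[j] = beta * V[j] + (rho if j == prev else 0.0)
            if u[j] > m:
                m = u[j]
        s = 0.0
        for j in range(4):
            u[j] = np.exp(u[j] - m)
            s += u[j]
        p = u[aj[t]] / s
        if p < 1e-300:
            p = 1e-300
        nll -= np.log(p)
        delta = rsum[t] - V[aj[t]]
        V[aj[t]] += alpha * delta
        prev = aj[t]
    return nll


@njit(cache=True)
def trace_joint(aj, rsum, newblock, alpha, beta, rho,
                V_out, delta_out, p_out, pch_out):
    """Joint-action recursion with latents: V_out (T,4) pre-update values,
    delta_out (T,) scalar prediction error, p_out (T,4) choice
    probabilities, pch_out (T,) probability of the chosen joint action."""
    T = aj.shape[0]
    V = np.zeros(4)
    prev = -1
    nll = 0.0
    u = np.empty(4)
    for t in range(T):
        if newblock[t] == 1:
            V[:] = 0.0
            prev = -1
        for j in range(4):
            V_out[t, j] = V[j]
        m = -1e308
        for j in range(4):
            u[j] = beta * V[j] + (rho if j == prev else 0.0)
            if u[j] > m:
                m = u[j]
        s = 0.0
        for j in range(4):
            u[j] = np.exp(u[j] - m)
            s += u[j]
        for j in range(4):
            p_out[t, j] = u[j] / s
        p = p_out[t, aj[t]]
        if p < 1e-300:
            p = 1e-300
        pch_out[t] = p
        nll -= np.log(p)
        delta = rsum[t] - V[aj[t]]
        delta_out[t] = delta
        V[aj[t]] += alpha * delta
        prev = aj[t]
    return nll
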