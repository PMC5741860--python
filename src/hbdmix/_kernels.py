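"""Numba inner loops for the renewal HMM.

The transition kernel has the rank-one-plus-diagonal renewal form
``a(k,l) = s_k * [k==l] + (1 - s_k) * m_l`` with ``s_k = exp(-R_k * d)``:
a class-k segment survives the inter-marker distance d with exponential
survival, and on termination the new class is drawn from the mixing
proportions m (self-transitions allowed).  All recursions exploit this
structure and run in O(T*K).

Inter-marker distances are passed compressed: ``su`` holds the per-state
survival probabilities for each *unique* distance (n_unique, K) and
``group`` maps each interval to its row, so regular marker grids cost a
single row.  ``em_sweep`` fuses the forward pass, backward pass and the
Baum-Welch sufficient statistics into one call, accumulating the expected
stay/jump counts per (unique distance, state) cell so the M-step for the
rates only needs the compressed table.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def forward(em, su, group, mix):
    """Scaled forward pass; returns (alpha, c) with rows of alpha
    normalized and loglik = sum(log(c))."""
    T, K = em.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    s0 = 0.0
    for k in range(K):
        alpha[0, k] = mix[k] * em[0, k]
        s0 += alpha[0, k]
    c[0] = s0
    if s0 <= 0.0:
        return alpha, c
    for k in range(K):
        alpha[0, k] /= s0
    for t in range(1, T):
        g = group[t - 1]
        jump = 0.0
        for k in range(K):
            jump += alpha[t - 1, k] * (1.0 - su[g, k])
        st = 0.0
        for l in range(K):
            v = (alpha[t - 1, l] * su[g, l] + jump * mix[l]) * em[t, l]
            alpha[t, l] = v
            st += v
        c[t] = st
        if st <= 0.0:
            return alpha, c
        for l in range(K):
            alpha[t, l] /= st
    return alpha, c


@njit(cache=True, fastmath=True)
def backward(em, su, group, mix, c):
    """Scaled backward pass (same scaling constants as forward)."""
    T, K = em.shape
    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        g = group[t]
        dot = 0.0
        for l in range(K):
            dot += mix[l] * em[t + 1, l] * beta[t + 1, l]
        for k in range(K):
            vk = em[t + 1, k] * beta[t + 1, k]
            beta[t, k] = (su[g, k] * vk + (1.0 - su[g, k]) * dot) / c[t + 1]
    return beta


@njit(cache=True, fastmath=True)
def em_sweep(em, su, group, mix, n_groups):
    """Forward + backward + Baum-Welch statistics in one fused pass.

    Returns (ok, loglik, post0, entries, stay_w, jump_w) where ``post0`` is
    the posterior at the first marker, ``entries[l]`` the expected number of
    segment entries into class l across the chain interior (chromosome-start
    entry NOT included; it equals post0), and ``stay_w``/``jump_w`` are
    (n_groups, K) expected stay/jump counts per unique-distance cell.
    ``ok`` is the index of the first marker with zero total probability, or
    -1 when the sweep succeeded.
    """
    T, K = em.shape
    entries = np.zeros(K)
    stay_w = np.zeros((n_groups, K))
    jump_w = np.zeros((n_groups, K))
    post0 = np.zeros(K)
    alpha = np.empty((T, K))
    c = np.empty(T)
    # forward
    s0 = 0.0
    for k in range(K):
        alpha[0, k] = mix[k] * em[0, k]
        s0 += alpha[0, k]
    if s0 <= 0.0:
        return 0, 0.0, post0, entries, stay_w, jump_w
    c[0] = s0
    for k in range(K):
        alpha[0, k] /= s0
    for t in range(1, T):
        g = group[t - 1]
        jump = 0.0
        for k in range(K):
            jump += alpha[t - 1, k] * (1.0 - su[g, k])
        st = 0.0
        for l in range(K):
            v = (alpha[t - 1, l] * su[g, l] + jump * mix[l]) * em[t, l]
            alpha[t, l] = v
            st += v
        if st <= 0.0:
            return t, 0.0, post0, entries, stay_w, jump_w
        c[t] = st
        for l in range(K):
            alpha[t, l] /= st
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    # backward with on-the-fly statistics; only the current beta row is kept
    beta_next = np.ones(K)
    beta_cur = np.empty(K)
    v = np.empty(K)
    for t in range(T - 2, -1, -1):
        g = group[t]
        dot = 0.0
        for l in range(K):
            v[l] = em[t + 1, l] * beta_next[l] / c[t + 1]
            dot += mix[l] * v[l]
        u = 0.0
        gsum = 0.0
        for k in range(K):
            beta_cur[k] = su[g, k] * v[k] + (1.0 - su[g, k]) * dot
            u += alpha[t, k] * (1.0 - su[g, k])
            gsum += alpha[t, k] * beta_cur[k]
        for k in range(K):
            gamma_k = alpha[t, k] * beta_cur[k] / gsum
            ws = alpha[t, k] * su[g, k] * v[k] / gsum
            wj = gamma_k - ws
            if wj < 0.0:
                wj = 0.0
            stay_w[g, k] += ws
            jump_w[g, k] += wj
            entries[k] += mix[k] * v[k] * u / gsum
            if t == 0:
                post0[k] = gamma_k
        for k in range(K):
            beta_next[k] = beta_cur[k]
    if T == 1:
        for k in range(K):
            post0[k] = alpha[0, k]
    return -1, loglik, post0, entries, stay_w, jump_w


@njit(cache=True)  # no fastmath: the recursion legitimately carries -inf
def viterbi(log_em, su, group, mix):
    """Most probable state path (log-space); ties break to the lowest index."""
    T, K = log_em.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        lm = np.log(mix[k]) if mix[k] > 0.0 else -np.inf
        delta[0, k] = lm + log_em[0, k]
    for t in range(1, T):
        g = group[t - 1]
        for l in range(K):
            best = -np.inf
            arg = 0
            for k in range(K):
                a = (1.0 - su[g, k]) * mix[l]
                if k == l:
                    a += su[g, k]
                la = np.log(a) if a > 0.0 else -np.inf
                v = delta[t - 1, k] + la
                if v > best:  # strict: first (lowest) index wins ties
                    best = v
                    arg = k
            delta[t, l] = best + log_em[t, l]
            psi[t, l] = arg
    path = np.empty(T, dtype=np.int64)
    best = -np.inf
    arg = 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best
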