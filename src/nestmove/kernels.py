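"""Numba kernels for the two per-iteration hot loops of the sampler.

All randomness is injected as pre-drawn arrays (uniforms, normals) so that
kernels are pure functions of their inputs and the chain stays reproducible
from a single numpy Generator.

State coding matches :mod:`nestmove.model`: top layer 0 = traveling,
1 = area-restricted search; sub layer 0 = foraging, 1 = resting; emission
components (traveling, foraging, resting) = columns 0..2 of ``log_e``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -np.inf
LOG_HALF = np.log(0.5)


@njit(cache=True)
def _lse2(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    if a == NEG_INF:
        return NEG_INF
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def ffbs_track(log_ptop, move_ll, dive_off, log_e, log_psub, u_top, u_sub,
               s_top_out, k_sub_out):
    """Draw both discrete state layers of one track from their joint
    full conditional (locations and parameters fixed).

    Forward-filters the augmented chain z_t = (S'_t, K_t) — K_t being the
    sub-state after the last dive at or before interval t — with the dives
    of each interval folded into 2x2 log-space transfer matrices, then
    backward-samples z, then backward-samples the within-interval dive
    states conditioned on the entry and exit sub-states.  The track's first
    dive takes a uniform initial sub-state; the first interval a uniform
    top state.

    Returns the marginal log-likelihood over all discrete paths (movement,
    transition and dive terms; observation terms are state-free).
    """
    T = move_ll.shape[0]
    M = np.empty((T, 2, 2, 2))
    for t in range(T):
        for s in range(2):
            m00, m01, m10, m11 = 0.0, NEG_INF, NEG_INF, 0.0
            for u in range(dive_off[t], dive_off[t + 1]):
                if u == 0:
                    t00 = LOG_HALF
                    t01 = LOG_HALF
                    t10 = LOG_HALF
                    t11 = LOG_HALF
                else:
                    t00 = log_psub[s, 0, 0]
                    t01 = log_psub[s, 0, 1]
                    t10 = log_psub[s, 1, 0]
                    t11 = log_psub[s, 1, 1]
                if s == 0:
                    e0 = log_e[u, 0]
                    e1 = log_e[u, 0]
                else:
                    e0 = log_e[u, 1]
                    e1 = log_e[u, 2]
                n00 = _lse2(m00 + t00, m01 + t10) + e0
                n01 = _lse2(m00 + t01, m01 + t11) + e1
                n10 = _lse2(m10 + t00, m11 + t10) + e0
                n11 = _lse2(m10 + t01, m11 + t11) + e1
                m00, m01, m10, m11 = n00, n01, n10, n11
            M[t, s, 0, 0] = m00
            M[t, s, 0, 1] = m01
            M[t, s, 1, 0] = m10
            M[t, s, 1, 1] = m11

    alpha = np.empty((T, 2, 2))
    for s in range(2):
        for k in range(2):
            alpha[0, s, k] = (LOG_HALF + move_ll[0, s]
                              + _lse2(LOG_HALF + M[0, s, 0, k],
                                      LOG_HALF + M[0, s, 1, k]))
    for t in range(1, T):
        for s in range(2):
            for k in range(2):
                acc = NEG_INF
                for sp in range(2):
                    for kp in range(2):
                        acc = _lse2(acc, alpha[t - 1, sp, kp]
                                    + log_ptop[sp, s] + M[t, s, kp, k])
                alpha[t, s, k] = acc + move_ll[t, s]

    loglik = NEG_INF
    for s in range(2):
        for k in range(2):
            loglik = _lse2(loglik, alpha[T - 1, s, k])

    # backward sampling of z_t
    k_exit = np.empty(T, np.int64)
    w = np.empty(4)
    for s in range(2):
        for k in range(2):
            w[s * 2 + k] = alpha[T - 1, s, k]
    z = _sample_log4(w, u_top[T - 1])
    s_top_out[T - 1] = z // 2
    k_exit[T - 1] = z % 2
    for t in range(T - 2, -1, -1):
        s_next = s_top_out[t + 1]
        k_next = k_exit[t + 1]
        for sp in range(2):
            for kp in range(2):
                w[sp * 2 + kp] = (alpha[t, sp, kp] + log_ptop[sp, s_next]
                                  + M[t + 1, s_next, kp, k_next])
        z = _sample_log4(w, u_top[t])
        s_top_out[t] = z // 2
        k_exit[t] = z % 2

    # within-interval sub-state paths, conditioned on entry/exit states
    maxn = 0
    for t in range(T):
        n = dive_off[t + 1] - dive_off[t]
        if n > maxn:
            maxn = n
    f = np.empty((maxn, 2))
    for t in range(T):
        u0 = dive_off[t]
        u1 = dive_off[t + 1]
        n = u1 - u0
        if n == 0:
            continue
        s = s_top_out[t]
        k_enter = k_exit[t - 1] if t > 0 else 0
        for i in range(n):
            u = u0 + i
            if s == 0:
                e0 = log_e[u, 0]
                e1 = log_e[u, 0]
            else:
                e0 = log_e[u, 1]
                e1 = log_e[u, 2]
            if u == 0:
                f[i, 0] = LOG_HALF + e0
                f[i, 1] = LOG_HALF + e1
            elif i == 0:
                f[i, 0] = log_psub[s, k_enter, 0] + e0
                f[i, 1] = log_psub[s, k_enter, 1] + e1
            else:
                f[i, 0] = _lse2(f[i - 1, 0] + log_psub[s, 0, 0],
                                f[i - 1, 1] + log_psub[s, 1, 0]) + e0
                f[i, 1] = _lse2(f[i - 1, 0] + log_psub[s, 0, 1],
                                f[i - 1, 1] + log_psub[s, 1, 1]) + e1
        k_sub_out[u1 - 1] = k_exit[t]
        for i in range(n - 2, -1, -1):
            u = u0 + i
            k_next = k_sub_out[u + 1]
            w0 = f[i, 0] + log_psub[s, 0, k_next]
            w1 = f[i, 1] + log_psub[s, 1, k_next]
            m = w0 if w0 > w1 else w1
            p0 = np.exp(w0 - m)
            p1 = np.exp(w1 - m)
            k_sub_out[u] = 0 if u_sub[u] * (p0 + p1) < p0 else 1
    return loglik


@njit(cache=True)
def _sample_log4(logw, u):
    m = logw[0]
    for i in range(1, 4):
        if logw[i] > m:
            m = logw[i]
    tot = 0.0
    p = np.empty(4)
    for i in range(4):
        p[i] = np.exp(logw[i] - m)
        tot += p[i]
    target = u * tot
    acc = 0.0
    for i in range(4):
        acc += p[i]
        if target < acc:
            return i
    return 3


@njit(cache=True)
def _local_location_lp(y, i, T, s_top, gamma, cos_t, sin_t, sdx, sdy,
                       fix_off, fix_j, fix_x, fix_y, fix_sd):
    """Log full-conditional terms touching grid point i (constants dropped)."""
    lp = 0.0
    qlo = i - 1 if i - 1 >= 1 else 1
    qhi = i + 1 if i + 1 <= T - 1 else T - 1
    for q in range(qlo, qhi + 1):
        s = s_top[q - 1]
        dx = y[q, 0] - y[q - 1, 0]
        dy = y[q, 1] - y[q - 1, 1]
        mx = y[q, 0] + gamma[s] * (cos_t[s] * dx - sin_t[s] * dy)
        my = y[q, 1] + gamma[s] * (sin_t[s] * dx + cos_t[s] * dy)
        rx = (y[q + 1, 0] - mx) / sdx
        ry = (y[q + 1, 1] - my) / sdy
        lp += -0.5 * (rx * rx + ry * ry)
    for t in (i, i + 1):
        if t < 1 or t > T:
            continue
        for fidx in range(fix_off[t - 1], fix_off[t]):
            j = fix_j[fidx]
            mx = (1.0 - j) * y[t - 1, 0] + j * y[t, 0]
            my = (1.0 - j) * y[t - 1, 1] + j * y[t, 1]
            sd = fix_sd[fidx]
            rx = (fix_x[fidx] - mx) / sd
            ry = (fix_y[fidx] - my) / sd
            lp += -0.5 * (rx * rx + ry * ry)
    return lp


@njit(cache=True)
def metropolis_locations(y, s_top, gamma, cos_t, sin_t, sdx, sdy,
                         fix_off, fix_j, fix_x, fix_y, fix_sd,
                         scale, eps, u):
    """One random-walk Metropolis sweep over all grid locations (in place).

    Each point is perturbed isotropically by ``scale`` km and accepted on
    its local full conditional (the up-to-three process factors and the
    fixes of the two adjacent intervals).  Returns the number of accepted
    moves.
    """
    N = y.shape[0]
    T = N - 1
    n_acc = 0
    for i in range(N):
        lp0 = _local_location_lp(y, i, T, s_top, gamma, cos_t, sin_t, sdx, sdy,
                                 fix_off, fix_j, fix_x, fix_y, fix_sd)
        ox = y[i, 0]
        oy = y[i, 1]
        y[i, 0] = ox + scale * eps[i, 0]
        y[i, 1] = oy + scale * eps[i, 1]
        lp1 = _local_location_lp(y, i, T, s_top, gamma, cos_t, sin_t, sdx, sdy,
                                 fix_off, fix_j, fix_x, fix_y, fix_sd)
        if np.log(u[i]) < lp1 - lp0:
            n_acc += 1
        else:
            y[i, 0] = ox
            y[i, 1] = oy
    return n_acc


@njit(cache=True)
def dive_chain_marginal(rows, log_e, log_psub):
    """Marginal log-likelihood of one track's dive sequence over all
    sub-state paths, conditioning on the per-dive top states ``rows``.

    Used by the partially collapsed update of the sub-layer transition
    logits: integrating S'' out decouples the logits from the sampled
    sub-states (which carry no emission information inside traveling
    intervals) and restores mixing.
    """
    D = rows.shape[0]
    if D == 0:
        return 0.0
    s = rows[0]
    if s == 0:
        f0 = LOG_HALF + log_e[0, 0]
        f1 = LOG_HALF + log_e[0, 0]
    else:
        f0 = LOG_HALF + log_e[0, 1]
        f1 = LOG_HALF + log_e[0, 2]
    for u in range(1, D):
        s = rows[u]
        if s == 0:
            e0 = log_e[u, 0]
            e1 = log_e[u, 0]
        else:
            e0 = log_e[u, 1]
            e1 = log_e[u, 2]
        n0 = _lse2(f0 + log_psub[s, 0, 0], f1 + log_psub[s, 1, 0]) + e0
        n1 = _lse2(f0 + log_psub[s, 0, 1], f1 + log_psub[s, 1, 1]) + e1
        f0, f1 = n0, n1
    return _lse2(f0, f1)
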