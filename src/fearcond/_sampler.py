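"""Numba kernels for the hierarchical sampler.

The posterior is explored with adaptive Metropolis-within-Gibbs: every
scalar parameter is updated in turn with a Gaussian random-walk proposal on
an unconstrained scale (logit for [0,1]-bounded parameters, log for
positive ones) with the appropriate Jacobian corrections.  Proposal step
sizes adapt per component during warm-up (Robbins-Monro toward a 0.44
acceptance rate) and are frozen afterwards so the sampling phase leaves the
target invariant.

Model layout (per subject): ``[lr_role_0 .. lr_role_{R-1}, lapse,
(v0_cs_plus, v0_cs_minus), (jump)]``; group level: a (shape1, shape2) pair
per learning-rate/start/jump parameter and a (shape, inv_scale) pair for
the lapse.  Subject-level conditional densities require one pass over that
subject's trials; group-level conditionals use cached sufficient statistics
(sums of log-transformed subject parameters) and are O(1).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# likelihood


@njit(cache=True)
def _subject_loglik(row, n_roles, use_v0, use_jump,
                    cue, us, role, rating, ext_start,
                    logq, log1mq, update_on_missing):
    """Total log-likelihood of one subject's rating sequence."""
    lapse = row[n_roles]
    if use_v0:
        vp = row[n_roles + 1]
        vm = row[n_roles + 2]
    else:
        vp = 0.5
        vm = 0.5
    if use_jump:
        jump = row[n_roles + 1 + (2 if use_v0 else 0)]
    else:
        jump = 0.0

    T = cue.shape[0]
    ll = 0.0
    w = np.empty(9)
    for t in range(T):
        if t == ext_start:
            vm = vm + jump
            if vm > 1.0:
                vm = 1.0
        v = vp if cue[t] == 1 else vm
        r = rating[t]
        if r > 0:
            vc = v
            if vc < 1e-6:
                vc = 1e-6
            elif vc > 1.0 - 1e-6:
                vc = 1.0 - 1e-6
            a = 10.0 * vc - 1.0      # alpha - 1
            b = 9.0 - 10.0 * vc      # beta - 1
            m = -1.0e300
            for i in range(9):
                wi = a * logq[i] + b * log1mq[i]
                w[i] = wi
                if wi > m:
                    m = wi
            s = 0.0
            for i in range(9):
                w[i] = math.exp(w[i] - m)
                s += w[i]
            m2 = -1.0e300
            for i in range(9):
                w[i] = w[i] / s * lapse
                if w[i] > m2:
                    m2 = w[i]
            s2 = 0.0
            for i in range(9):
                s2 += math.exp(w[i] - m2)
            ll += w[r - 1] - m2 - math.log(s2)
        if r > 0 or update_on_missing:
            lr = row[role[t]]
            vnew = v + (us[t] - v) * lr
            if cue[t] == 1:
                vp = vnew
            else:
                vm = vnew
    return ll


@njit(cache=True)
def _pointwise_loglik_matrix(draws_sub, n_roles, use_v0, use_jump,
                             cue, us, role, rating, ext_start,
                             logq, log1mq, update_on_missing):
    """Per-draw, per-datapoint log-likelihood matrix.

    Datapoints are the non-missing (subject, trial) pairs in subject-major
    order.
    """
    D = draws_sub.shape[0]
    N = cue.shape[0]
    T = cue.shape[1]
    n_points = 0
    for i in range(N):
        for t in range(T):
            if rating[i, t] > 0:
                n_points += 1
    out = np.empty((D, n_points))
    w = np.empty(9)
    for d in range(D):
        p = 0
        for i in range(N):
            row = draws_sub[d, i]
            lapse = row[n_roles]
            if use_v0:
                vp = row[n_roles + 1]
                vm = row[n_roles + 2]
            else:
                vp = 0.5
                vm = 0.5
            if use_jump:
                jump = row[n_roles + 1 + (2 if use_v0 else 0)]
            else:
                jump = 0.0
            for t in range(T):
                if t == ext_start[i]:
                    vm = vm + jump
                    if vm > 1.0:
                        vm = 1.0
                v = vp if cue[i, t] == 1 else vm
                r = rating[i, t]
                if r > 0:
                    vc = min(max(v, 1e-6), 1.0 - 1e-6)
                    a = 10.0 * vc - 1.0
                    b = 9.0 - 10.0 * vc
                    m = -1.0e300
                    for k in range(9):
                        wk = a * logq[k] + b * log1mq[k]
                        w[k] = wk
                        if wk > m:
                            m = wk
                    s = 0.0
                    for k in range(9):
                        w[k] = math.exp(w[k] - m)
                        s += w[k]
                    m2 = -1.0e300
                    for k in range(9):
                        w[k] = w[k] / s * lapse
                        if w[k] > m2:
                            m2 = w[k]
                    s2 = 0.0
                    for k in range(9):
                        s2 += math.exp(w[k] - m2)
                    out[d, p] = w[r - 1] - m2 - math.log(s2)
                    p += 1
                if r > 0 or update_on_missing:
                    lr = row[role[i, t]]
                    vnew = v + (us[i, t] - v) * lr
                    if cue[i, t] == 1:
                        vp = vnew
                    else:
                        vm = vnew
    return out


# ---------------------------------------------------------------------------
# priors


@njit(cache=True)
def _lbeta(a, b):
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def _gamma_logpdf(x, shape, rate):
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x


@njit(cache=True)
def _beta_logpdf(x, a, b):
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x) - _lbeta(a, b)


@njit(cache=True)
def _log_joint(con_sub, con_hyp, n_roles, use_v0, use_jump,
               cue, us, role, rating, ext_start,
               lr_a0, lr_b0, lapse_a0, lapse_b0,
               logq, log1mq, update_on_missing):
    """Full joint log-density on the constrained scale (no Jacobians):
    hyperpriors + subject-level priors + trial likelihood."""
    N, P = con_sub.shape
    H = con_hyp.shape[0]
    lp = 0.0
    for h in range(H):
        if h == 2 * n_roles or h == 2 * n_roles + 1:
            lp += _gamma_logpdf(con_hyp[h], lapse_a0, lapse_b0)
        else:
            lp += _gamma_logpdf(con_hyp[h], lr_a0, lr_b0)
    for i in range(N):
        for j in range(P):
            x = con_sub[i, j]
            if j == n_roles:
                lp += _gamma_logpdf(x, con_hyp[2 * n_roles], con_hyp[2 * n_roles + 1])
            else:
                # hyper pairs are laid out in subject-parameter order
                lp += _beta_logpdf(x, con_hyp[2 * j] + 1.0, con_hyp[2 * j + 1] + 1.0)
        lp += _subject_loglik(con_sub[i], n_roles, use_v0, use_jump,
                              cue[i], us[i], role[i], rating[i], ext_start[i],
                              logq, log1mq, update_on_missing)
    return lp


# ---------------------------------------------------------------------------
# chain


@njit(cache=True)
def _run_chain(cue, us, role, rating, ext_start,
               n_roles, use_v0, use_jump,
               lr_a0, lr_b0, lapse_a0, lapse_b0,
               warmup, samples, subj_scans, hyper_scans,
               target_accept, seed,
               logq, log1mq, update_on_missing):
    """One MCMC chain.  Returns (subject draws, hyper draws, accept rates)."""
    np.random.seed(seed)
    N = cue.shape[0]
    P = n_roles + 1 + (2 if use_v0 else 0) + (1 if use_jump else 0)
    H = 2 * P

    # hyper pair base index for each subject parameter
    pair_base = np.empty(P, dtype=np.int64)
    for j in range(P):
        pair_base[j] = 2 * j

    # --- initial state (unconstrained)
    z_sub = np.empty((N, P))
    for i in range(N):
        for j in range(P):
            z_sub[i, j] = 0.5 * np.random.normal()
    z_hyp = np.empty(H)
    for h in range(H):
        if h == 2 * n_roles or h == 2 * n_roles + 1:
            z_hyp[h] = math.log(5.0) + 0.3 * np.random.normal()
        else:
            z_hyp[h] = math.log(0.5) + 0.3 * np.random.normal()

    con_sub = np.empty((N, P))
    for i in range(N):
        for j in range(P):
            if j == n_roles:
                con_sub[i, j] = math.exp(z_sub[i, j])
            else:
                con_sub[i, j] = 1.0 / (1.0 + math.exp(-z_sub[i, j]))
    con_hyp = np.exp(z_hyp)

    # cached sufficient statistics
    slog = np.zeros(P)      # sum_i log x_ij           (beta params)
    slog1m = np.zeros(P)    # sum_i log (1 - x_ij)     (beta params)
    s_lapse = 0.0
    s_log_lapse = 0.0
    for i in range(N):
        for j in range(P):
            if j == n_roles:
                s_lapse += con_sub[i, j]
                s_log_lapse += math.log(con_sub[i, j])
            else:
                slog[j] += math.log(con_sub[i, j])
                slog1m[j] += math.log(1.0 - con_sub[i, j])

    cur_ll = np.empty(N)
    for i in range(N):
        cur_ll[i] = _subject_loglik(con_sub[i], n_roles, use_v0, use_jump,
                                    cue[i], us[i], role[i], rating[i], ext_start[i],
                                    logq, log1mq, update_on_missing)

    ls_sub = np.full((N, P), math.log(0.5))
    ls_hyp = np.full(H, math.log(0.3))

    draws_sub = np.empty((samples, N, P))
    draws_hyp = np.empty((samples, H))
    acc_sub = 0.0
    try_sub = 0.0
    acc_hyp = 0.0
    try_hyp = 0.0

    tmp = np.empty(P)
    # interleave group-level sweeps between subject-level sweeps so the
    # cheap hyper updates see fresh subject states
    hyper_per_block = hyper_scans // subj_scans
    if hyper_per_block < 1:
        hyper_per_block = 1
    total_iters = warmup + samples
    for it in range(total_iters):
        adapting = it < warmup
        g = 2.0 / math.sqrt(1.0 + it) if adapting else 0.0
        if g > 0.25:
            g = 0.25

        # ---- subject-level scans
        for _ in range(subj_scans):
            for i in range(N):
                for j in range(P):
                    z = z_sub[i, j]
                    zp = z + math.exp(ls_sub[i, j]) * np.random.normal()
                    if abs(zp) > 30.0:
                        alpha = 0.0
                    else:
                        for k in range(P):
                            tmp[k] = con_sub[i, k]
                        if j == n_roles:
                            xp = math.exp(zp)
                        else:
                            xp = 1.0 / (1.0 + math.exp(-zp))
                        tmp[j] = xp
                        x = con_sub[i, j]
                        if j == n_roles:
                            sh = con_hyp[2 * n_roles]
                            rt = con_hyp[2 * n_roles + 1]
                            dprior = (sh * math.log(xp) - rt * xp) - (sh * math.log(x) - rt * x)
                        else:
                            b0 = pair_base[j]
                            s1 = con_hyp[b0]
                            s2 = con_hyp[b0 + 1]
                            dprior = ((s1 + 1.0) * math.log(xp) + (s2 + 1.0) * math.log(1.0 - xp)) \
                                - ((s1 + 1.0) * math.log(x) + (s2 + 1.0) * math.log(1.0 - x))
                        llp = _subject_loglik(tmp, n_roles, use_v0, use_jump,
                                              cue[i], us[i], role[i], rating[i], ext_start[i],
                                              logq, log1mq, update_on_missing)
                        delta = llp - cur_ll[i] + dprior
                        alpha = 1.0 if delta >= 0.0 else math.exp(delta)
                    try_sub += 1.0
                    if np.random.random() < alpha:
                        acc_sub += 1.0
                        if j == n_roles:
                            s_lapse += xp - con_sub[i, j]
                            s_log_lapse += math.log(xp) - math.log(con_sub[i, j])
                        else:
                            slog[j] += math.log(xp) - math.log(con_sub[i, j])
                            slog1m[j] += math.log(1.0 - xp) - math.log(1.0 - con_sub[i, j])
                        z_sub[i, j] = zp
                        con_sub[i, j] = xp
                        cur_ll[i] = llp
                    if adapting:
                        ls_sub[i, j] += g * (alpha - target_accept)

            # ---- group-level scans (O(1) via cached sums), interleaved so
            # they see fresh subject states
            for _ in range(hyper_per_block):
                for h in range(H):
                    z = z_hyp[h]
                    zp = z + math.exp(ls_hyp[h]) * np.random.normal()
                    if abs(zp) > 30.0:
                        alpha = 0.0
                    else:
                        sp = math.exp(zp)
                        s = con_hyp[h]
                        is_lapse_pair = h == 2 * n_roles or h == 2 * n_roles + 1
                        if is_lapse_pair:
                            a0 = lapse_a0
                            b0p = lapse_b0
                        else:
                            a0 = lr_a0
                            b0p = lr_b0
                        # prior + log-transform Jacobian
                        dlp = (a0 * zp - b0p * sp) - (a0 * z - b0p * s)
                        if is_lapse_pair:
                            sh = con_hyp[2 * n_roles]
                            rt = con_hyp[2 * n_roles + 1]
                            if h == 2 * n_roles:
                                dlp += (N * (sp * math.log(rt) - math.lgamma(sp)) + sp * s_log_lapse) \
                                    - (N * (sh * math.log(rt) - math.lgamma(sh)) + sh * s_log_lapse)
                            else:
                                dlp += (N * sh * math.log(sp) - sp * s_lapse) \
                                    - (N * sh * math.log(rt) - rt * s_lapse)
                        else:
                            j = h // 2
                            first = h % 2 == 0
                            s1 = con_hyp[2 * j]
                            s2 = con_hyp[2 * j + 1]
                            if first:
                                dlp += (sp * slog[j] - N * _lbeta(sp + 1.0, s2 + 1.0)) \
                                    - (s1 * slog[j] - N * _lbeta(s1 + 1.0, s2 + 1.0))
                            else:
                                dlp += (sp * slog1m[j] - N * _lbeta(s1 + 1.0, sp + 1.0)) \
                                    - (s2 * slog1m[j] - N * _lbeta(s1 + 1.0, s2 + 1.0))
                        alpha = 1.0 if dlp >= 0.0 else math.exp(dlp)
                    try_hyp += 1.0
                    if np.random.random() < alpha:
                        acc_hyp += 1.0
                        z_hyp[h] = zp
                        con_hyp[h] = math.exp(zp)
                    if adapting:
                        ls_hyp[h] += g * (alpha - target_accept)

        if it >= warmup:
            d = it - warmup
            for i in range(N):
                for j in range(P):
                    draws_sub[d, i, j] = con_sub[i, j]
            for h in range(H):
                draws_hyp[d, h] = con_hyp[h]

    return draws_sub, draws_hyp, acc_sub / max(try_sub, 1.0), acc_hyp / max(try_hyp, 1.0)
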