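"""Numba-accelerated latent-trajectory sweep.

The latent update visits every (month, component) site with a symmetric
integer random-walk proposal.  This kernel is a serial scalar mirror of
``IPMModel.site_delta``; proposals and uniforms are drawn *outside* (from
the caller's Generator) so the kernel is deterministic given its inputs and
can be checked draw-for-draw against the pure-Python reference path.

If numba is unavailable the package falls back to the (slower) reference
implementation; results remain valid MCMC either way.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco

_NEG_INF = -np.inf
_P_EPS = 1e-12


@njit(cache=True)
def _clamp(p):
    if p < _P_EPS:
        return _P_EPS
    if p > 1.0 - _P_EPS:
        return 1.0 - _P_EPS
    return p


@njit(cache=True)
def _binom_lp(k, n, p):
    if k < 0 or n < 0 or k > n:
        return _NEG_INF
    p = _clamp(p)
    return (
        math.lgamma(n + 1.0)
        - math.lgamma(k + 1.0)
        - math.lgamma(n - k + 1.0)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def _trinom_lp(x1, x2, n, p1, p2):
    x3 = n - x1 - x2
    if x1 < 0 or x2 < 0 or x3 < 0 or n < 0:
        return _NEG_INF
    p1 = _clamp(p1)
    p2 = _clamp(p2)
    p3 = _clamp(1.0 - p1 - p2)
    return (
        math.lgamma(n + 1.0)
        - math.lgamma(x1 + 1.0)
        - math.lgamma(x2 + 1.0)
        - math.lgamma(x3 + 1.0)
        + x1 * math.log(p1)
        + x2 * math.log(p2)
        + x3 * math.log(p3)
    )


@njit(cache=True)
def _nbinom_lp(k, mean, s2):
    if mean <= 0.0:
        return 0.0 if k == 0 else _NEG_INF
    if k < 0:
        return _NEG_INF
    alpha = mean * mean / s2
    beta = mean / s2
    return (
        math.lgamma(k + alpha)
        - math.lgamma(alpha)
        - math.lgamma(k + 1.0)
        + alpha * math.log(beta / (1.0 + beta))
        - k * math.log1p(beta)
    )


@njit(cache=True)
def _norm_lp(x, mu, var):
    return -0.5 * (math.log(2.0 * math.pi * var) + (x - mu) ** 2 / var)


@njit(cache=True)
def _gamma_lp_mv(x, mean, var):
    if x <= 0.0 or mean <= 0.0:
        return _NEG_INF
    shape = mean * mean / var
    rate = mean / var
    return (
        shape * math.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


@njit(cache=True)
def _obs_class(c):
    if c == 0:
        return 0
    if c <= 5:
        return 1
    if c <= 18:
        return 2
    if c <= 31:  # P classes and Fa
        return 3
    return 4


@njit(cache=True)
def _site_dll(c, t, d, T, traj, tot, B, r, sq, sh, saf, sam, phi,
              ground, sig, init_means, init_var, aidx, K, lamT, sigmaT_sq):
    old = traj[t, c]
    new = old + d
    if new < 0:
        return _NEG_INF
    dll = 0.0
    # observation factor (months 1..T)
    if t >= 1:
        cls = _obs_class(c)
        cnt = ground[t - 1, cls]
        dll += _nbinom_lp(cnt, tot[t, cls] + d, sig[cls]) - _nbinom_lp(
            cnt, tot[t, cls], sig[cls]
        )
    # aerial factor when month t hosts a survey
    j = aidx[t]
    if j >= 0:
        dll += _gamma_lp_mv(lamT[j], K[j] * (B[t] + d), sigmaT_sq) - _gamma_lp_mv(
            lamT[j], K[j] * B[t], sigmaT_sq
        )

    pool = traj[t, 29] + traj[t, 30]  # P11 + P12
    if c == 0:  # newborns
        dll += _binom_lp(new, pool, r[t]) - _binom_lp(old, pool, r[t])
        if t < T:
            dll += _binom_lp(traj[t + 1, 19], new, saf[t + 1]) - _binom_lp(
                traj[t + 1, 19], old, saf[t + 1]
            )
            dll += _binom_lp(traj[t + 1, 1], new, sq[t + 1]) - _binom_lp(
                traj[t + 1, 1], old, sq[t + 1]
            )
            dll += _binom_lp(traj[t + 1, 30], pool - new, saf[t + 1]) - _binom_lp(
                traj[t + 1, 30], pool - old, saf[t + 1]
            )
    elif c <= 18:  # juvenile cohort G(k), k = c + 1
        k = c + 1
        if t >= 1:
            trials = traj[t - 1, c - 1]
            s_in = sq[t] if k <= 6 else sh[t]
            dll += _binom_lp(new, trials, s_in) - _binom_lp(old, trials, s_in)
        else:
            dll += _norm_lp(new, init_means[c], init_var) - _norm_lp(
                old, init_means[c], init_var
            )
        if t < T:
            if k < 19:
                s_out = sq[t + 1] if (k + 1) <= 6 else sh[t + 1]
                outc = traj[t + 1, c + 1]
                dll += _binom_lp(outc, new, s_out) - _binom_lp(outc, old, s_out)
            else:
                p1 = phi[t + 1] * saf[t + 1]
                p2 = (1.0 - phi[t + 1]) * sam[t + 1]
                fa = traj[t + 1, 31]
                ma = traj[t + 1, 32]
                dll += _trinom_lp(fa, ma, new, p1, p2) - _trinom_lp(
                    fa, ma, old, p1, p2
                )
    elif c <= 30:  # pregnancy class P(l), l = c - 18
        l = c - 18
        if t >= 1:
            if l == 1:
                trials = traj[t - 1, 0]
            elif l == 4:
                trials = traj[t - 1, 21] + traj[t - 1, 31]
            elif l == 12:
                trials = traj[t - 1, 29] + traj[t - 1, 30] - traj[t - 1, 0]
            else:
                trials = traj[t - 1, c - 1]
            dll += _binom_lp(new, trials, saf[t]) - _binom_lp(old, trials, saf[t])
        else:
            dll += _norm_lp(new, init_means[c], init_var) - _norm_lp(
                old, init_means[c], init_var
            )
        if l >= 11:  # same-month birth pool
            Nt = traj[t, 0]
            dll += _binom_lp(Nt, pool + d, r[t]) - _binom_lp(Nt, pool, r[t])
        if t < T:
            if l == 3:
                outc = traj[t + 1, 22]
                tr_old = old + traj[t, 31]
                dll += _binom_lp(outc, tr_old + d, saf[t + 1]) - _binom_lp(
                    outc, tr_old, saf[t + 1]
                )
            elif l < 11:
                outc = traj[t + 1, c + 1]
                dll += _binom_lp(outc, new, saf[t + 1]) - _binom_lp(
                    outc, old, saf[t + 1]
                )
            else:  # l in (11, 12): next-month conceivable pool
                outc = traj[t + 1, 30]
                tr_old = pool - traj[t, 0]
                dll += _binom_lp(outc, tr_old + d, saf[t + 1]) - _binom_lp(
                    outc, tr_old, saf[t + 1]
                )
    elif c == 31:  # Fa
        if t >= 1:
            p1 = phi[t] * saf[t]
            p2 = (1.0 - phi[t]) * sam[t]
            g19 = traj[t - 1, 18]
            ma = traj[t, 32]
            dll += _trinom_lp(new, ma, g19, p1, p2) - _trinom_lp(
                old, ma, g19, p1, p2
            )
        else:
            dll += _norm_lp(new, init_means[c], init_var) - _norm_lp(
                old, init_means[c], init_var
            )
        if t < T:
            outc = traj[t + 1, 22]
            tr_old = traj[t, 21] + old
            dll += _binom_lp(outc, tr_old + d, saf[t + 1]) - _binom_lp(
                outc, tr_old, saf[t + 1]
            )
    elif c == 32:  # Ma
        if t >= 1:
            p1 = phi[t] * saf[t]
            p2 = (1.0 - phi[t]) * sam[t]
            g19 = traj[t - 1, 18]
            fa = traj[t, 31]
            dll += _trinom_lp(fa, new, g19, p1, p2) - _trinom_lp(
                fa, old, g19, p1, p2
            )
        else:
            dll += _norm_lp(new, init_means[c], init_var) - _norm_lp(
                old, init_means[c], init_var
            )
        if t < T:
            outc = traj[t + 1, 33]
            tr_old = old + traj[t, 33]
            dll += _binom_lp(outc, tr_old + d, sam[t + 1]) - _binom_lp(
                outc, tr_old, sam[t + 1]
            )
    else:  # c == 33, Mb
        if t >= 1:
            trials = traj[t - 1, 32] + traj[t - 1, 33]
            dll += _binom_lp(new, trials, sam[t]) - _binom_lp(old, trials, sam[t])
        else:
            dll += _norm_lp(new, init_means[c], init_var) - _norm_lp(
                old, init_means[c], init_var
            )
        if t < T:
            outc = traj[t + 1, 33]
            tr_old = traj[t, 32] + old
            dll += _binom_lp(outc, tr_old + d, sam[t + 1]) - _binom_lp(
                outc, tr_old, sam[t + 1]
            )
    return dll


@njit(cache=True)
def sweep_kernel(traj, tot, B, T, r, sq, sh, saf, sam, phi, ground, sig,
                 init_means, init_var, aidx, K, lamT, sigmaT_sq,
                 d_arr, logu, comps):
    """Serial Metropolis sweep over all sites; mutates traj/tot/B in place."""
    acc = np.zeros(34, dtype=np.int64)
    for ci in range(len(comps)):
        c = comps[ci]
        for t in range(T + 1):
            d = d_arr[c, t]
            if d == 0:
                continue
            dll = _site_dll(c, t, d, T, traj, tot, B, r, sq, sh, saf, sam,
                            phi, ground, sig, init_means, init_var, aidx, K,
                            lamT, sigmaT_sq)
            if logu[c, t] < dll:
                traj[t, c] += d
                tot[t, _obs_class(c)] += d
                B[t] += d
                acc[c] += 1
    return acc
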