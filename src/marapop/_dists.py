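"""Vectorized log-probability kernels used throughout the likelihood.

The MCMC sweep evaluates thousands of binomial/negative-binomial terms on
short arrays per iteration; the frozen-distribution machinery of
``scipy.stats`` costs tens of microseconds per call, which would dominate the
run time.  These kernels are plain ``gammaln`` arithmetic with exactly the
same conventions, and the test suite checks them against ``scipy.stats``.

Infeasible support (k < 0, k > n, n < 0) maps to -inf rather than raising,
because the samplers use -inf to encode constraint violations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_P_EPS = 1e-12


def clamp_prob(p):
    """Clamp probabilities into the open interval (1e-12, 1 - 1e-12)."""
    return np.clip(p, _P_EPS, 1.0 - _P_EPS)


def binom_logpmf(k, n, p):
    """log P[Binomial(n, p) = k]; -inf outside the support."""
    k = np.asarray(k, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    p = clamp_prob(np.asarray(p, dtype=np.float64))
    ok = (k >= 0) & (k <= n) & (n >= 0)
    kk = np.where(ok, k, 0.0)
    nn = np.where(ok, n, 1.0)
    out = (
        gammaln(nn + 1.0)
        - gammaln(kk + 1.0)
        - gammaln(nn - kk + 1.0)
        + kk * np.log(p)
        + (nn - kk) * np.log1p(-p)
    )
    return np.where(ok, out, -np.inf)


def trinomial_logpmf(x1, x2, n, p1, p2):
    """log-pmf of the first two cells of Multinomial(n; p1, p2, 1-p1-p2)."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    p1 = clamp_prob(np.asarray(p1, dtype=np.float64))
    p2 = clamp_prob(np.asarray(p2, dtype=np.float64))
    p3 = clamp_prob(1.0 - p1 - p2)
    x3 = n - x1 - x2
    ok = (x1 >= 0) & (x2 >= 0) & (x3 >= 0) & (n >= 0)
    a = np.where(ok, x1, 0.0)
    b = np.where(ok, x2, 0.0)
    c = np.where(ok, x3, 0.0)
    nn = np.where(ok, n, 0.0)
    out = (
        gammaln(nn + 1.0)
        - gammaln(a + 1.0)
        - gammaln(b + 1.0)
        - gammaln(c + 1.0)
        + a * np.log(p1)
        + b * np.log(p2)
        + c * np.log(p3)
    )
    return np.where(ok, out, -np.inf)


def poisson_logpmf(k, lam):
    k = np.asarray(k, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    ok = (k >= 0) & (lam > 0)
    kk = np.where(ok, k, 0.0)
    ll = np.where(ok, lam, 1.0)
    out = kk * np.log(ll) - ll - gammaln(kk + 1.0)
    # lam == 0 is a point mass at zero
    zero = (lam == 0) & (k == 0)
    return np.where(zero, 0.0, np.where(ok, out, -np.inf))


def norm_logpdf(x, mean, var):
    x = np.asarray(x, dtype=np.float64)
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def gamma_logpdf_mean_var(x, mean, var):
    """Gamma log-density parameterized by mean and variance.

    shape = mean^2/var, rate = mean/var; -inf off support or for mean <= 0.
    """
    x = np.asarray(x, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64)
    var = np.asarray(var, dtype=np.float64)
    ok = (x > 0) & (mean > 0) & (var > 0)
    xx = np.where(ok, x, 1.0)
    mm = np.where(ok, mean, 1.0)
    vv = np.where(ok, var, 1.0)
    shape = mm * mm / vv
    rate = mm / vv
    out = shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(xx) - rate * xx
    return np.where(ok, out, -np.inf)


def nbinom_logpmf_mean_var(k, mean, sigma_sq):
    """Gamma-Poisson mixture log-pmf with E = mean, Var = mean + sigma_sq.

    This is the analytic marginal of lambda ~ Gamma(mean^2/s2, mean/s2),
    count ~ Poisson(lambda): a negative binomial with size mean^2/s2 and
    success probability beta/(1+beta), beta = mean/s2.  A zero mean is the
    degenerate point mass at zero.
    """
    k = np.asarray(k, dtype=np.float64)
    mean = np.asarray(mean, dtype=np.float64)
    sigma_sq = np.asarray(sigma_sq, dtype=np.float64)
    pos = mean > 0
    ok = (k >= 0) & pos & (sigma_sq > 0)
    kk = np.where(ok, k, 0.0)
    mm = np.where(ok, mean, 1.0)
    ss = np.where(ok, sigma_sq, 1.0)
    alpha = mm * mm / ss
    beta = mm / ss
    out = (
        gammaln(kk + alpha)
        - gammaln(alpha)
        - gammaln(kk + 1.0)
        + alpha * np.log(beta / (1.0 + beta))
        - kk * np.log1p(beta)
    )
    zero = (~pos) & (k == 0)
    return np.where(zero, 0.0, np.where(ok, out, -np.inf))
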