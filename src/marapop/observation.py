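"""Gamma-Poisson ground-count observation layer and aerial integration.

Each observed class count is Poisson with a gamma-distributed intensity
centred on the latent class total:  lambda ~ Gamma(Y^2/sigma^2, Y/sigma^2),
count | lambda ~ Poisson(lambda), so counts are unbiased for the state with
variance Y + sigma^2 (overdispersed relative to Poisson).  The gamma
intensity is marginalized analytically in the log-density (negative-binomial
form); simulation keeps the two-stage draw.

Aerial surveys estimate the ecosystem-wide total.  The reserve total B links
to the ecosystem total through a survey-specific ratio K > 1:
lambda_T ~ Gamma(mean K*B, var sigma_T^2), true total mho ~ Poisson(lambda_T)
and the published estimate psi ~ Normal(mho, sigma_psi^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dists import (
    gamma_logpdf_mean_var,
    nbinom_logpmf_mean_var,
    norm_logpdf,
    poisson_logpmf,
)
from .states import StateVector, class_totals

NEWBORN_CORRECTION = 1.7


@dataclass(frozen=True)
class GroundObservation:
    """Monthly class counts (newborn, quarter, half-yearling, adult F/M)."""

    n: int
    q: int
    h: int
    f: int
    m: int

    def __post_init__(self):
        for name in ("n", "q", "h", "f", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.q, self.h, self.f, self.m], dtype=np.int64)


@dataclass(frozen=True)
class AerialObservation:
    month_index: int
    psi: float
    se: float

    def __post_init__(self):
        if self.psi < 0:
            raise ValueError("aerial estimate must be non-negative")
        if self.se <= 0:
            raise ValueError("aerial standard error must be positive")


@dataclass
class VarianceParams:
    """Observation variance offsets (per ground class, aerial chain)."""

    sigma_sq: np.ndarray  # length 5, ground classes
    sigmaT_sq: float
    sigmaPsi_sq: float

    def __post_init__(self):
        self.sigma_sq = np.asarray(self.sigma_sq, dtype=float)
        if self.sigma_sq.shape != (5,) or np.any(self.sigma_sq <= 0):
            raise ValueError("sigma_sq must be 5 positive values")
        if self.sigmaT_sq <= 0 or self.sigmaPsi_sq <= 0:
            raise ValueError("sigmaT_sq and sigmaPsi_sq must be positive")


def gamma_parameters(mean_count: float, sigma_sq: float):
    """(shape, rate) of the intensity gamma: mean = mean_count, var = sigma_sq.

    A zero mean is degenerate (intensity exactly 0); returns (0.0, 0.0).
    """
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be positive")
    if mean_count < 0:
        raise ValueError("mean_count must be non-negative")
    if mean_count == 0:
        return (0.0, 0.0)
    return (mean_count ** 2 / sigma_sq, mean_count / sigma_sq)


def gamma_poisson_draws(mean, sigma_sq, size, rng) -> np.ndarray:
    """Vectorized two-stage gamma-Poisson count draws (mean, var mean+s2)."""
    mean = float(mean)
    if mean == 0:
        if size is None:
            return np.int64(0)
        return np.zeros(size, dtype=np.int64)
    shape, rate = gamma_parameters(mean, sigma_sq)
    lam = rng.gamma(shape, 1.0 / rate, size=size)
    return rng.poisson(lam)


def counts_from_classes(classes, v: VarianceParams, rng) -> GroundObservation:
    """Draw one month's ground counts from five latent class totals."""
    classes = np.asarray(classes, dtype=float)
    draws = [
        int(gamma_poisson_draws(classes[i], v.sigma_sq[i], None, rng))
        for i in range(5)
    ]
    return GroundObservation(*draws)


def simulate_ground_obs(Y: StateVector, v: VarianceParams, rng) -> GroundObservation:
    """Ground counts for one month given the latent state."""
    totals = np.array([Y.N, Y.Q, Y.H, Y.F, Y.M], dtype=float)
    return counts_from_classes(totals, v, rng)


def ground_obs_logdensity(z: GroundObservation, Y: StateVector, v: VarianceParams) -> float:
    """Marginal (negative-binomial) log-density of one month's counts."""
    counts = z.as_array()
    totals = np.array([Y.N, Y.Q, Y.H, Y.F, Y.M], dtype=float)
    return float(np.sum(nbinom_logpmf_mean_var(counts, totals, v.sigma_sq)))


def ground_loglik_trajectory(counts: np.ndarray, traj: np.ndarray,
                             sigma_sq: np.ndarray, per_class: bool = False):
    """Vectorized ground log-likelihood for months 1..T.

    ``counts`` is (T, 5); ``traj`` is the (T+1, 34) latent trajectory.
    """
    totals = class_totals(traj)[1:]
    ll = nbinom_logpmf_mean_var(np.asarray(counts, float), totals,
                                np.asarray(sigma_sq, float)[None, :])
    if per_class:
        return ll.sum(axis=0)
    return float(ll.sum())


def aerial_logdensity(
    obs: AerialObservation,
    K: float,
    lamT: float,
    mho: int,
    B: int,
    sigmaT_sq: float,
    sigmaPsi_sq: float,
) -> float:
    """Joint log-density of the aerial chain at one survey month.

    Gamma(lamT; mean K*B, var sigmaT^2) + Poisson(mho | lamT)
    + Normal(psi | mho, sigmaPsi^2).  K <= 1 is outside the prior support.
    """
    if K <= 1.0:
        return -np.inf
    lg = gamma_logpdf_mean_var(lamT, K * max(B, 0), sigmaT_sq)
    lp = poisson_logpmf(mho, lamT)
    ln = norm_logpdf(obs.psi, mho, sigmaPsi_sq)
    return float(lg + lp + ln)


def correct_newborn_count(n) -> float:
    """Sightability correction applied to raw newborn counts (screening only).

    Hidden calves make raw newborn counts biased low; the corrected count is
    1.7 * n.  Used when deriving starting coefficient values, never inside
    the MCMC likelihood.
    """
    n = np.asarray(n)
    if np.any(n < 0):
        raise ValueError("counts must be non-negative")
    return NEWBORN_CORRECTION * n
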