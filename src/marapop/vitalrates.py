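"""Logit vital-rate models and the predation/seasonality adjustment.

Natural (predation-free) monthly rates come from linear logit models on the
covariate table: birth recruitment r, quarter survival s_q, half-yearling
survival s_h, adult survival s_a and the probability phi that a recruit
graduating to adulthood is female.  Month and season enter the survival and
sex-ratio models as indicator (Dirac) selections of a per-month or per-season
intercept.

Predation is factored out of survival multiplicatively,
P(survive) = P(survive natural causes) * (1 - predation risk), with the risk
scaled down during the dry season (Jul-Oct) when migratory prey flood the
system, and adult male survival set to a fixed fraction of adult female
survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .covariates import CovariateTable, DRY_MONTHS

_EPS = 1e-12

BLOCK_SIZES = {"R": 9, "Q": 14, "H": 13, "A": 8, "S": 9}


def inverse_logit(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    return expit(x)


def _clamp(p):
    return np.clip(p, _EPS, 1.0 - _EPS)


@dataclass
class VitalRateCoefficients:
    """Coefficient vectors of the five logit models (Table-4 layout)."""

    gammaR: np.ndarray  # intercept, month, month^2, month^3, rain, rain^2, Npop, mintemp, maxtemp
    gammaQ: np.ndarray  # 12 month intercepts + dry1 + mavrain_3_4
    gammaH: np.ndarray  # 12 month intercepts + earlywet1
    gammaA: np.ndarray  # 2 season intercepts + Apop + lagrain4..7 + wet1
    gammaS: np.ndarray  # 2 season intercepts + wet1 + dry1 + lagrain0 + rain + mintemp + lagmin2 + lagmax1

    def __post_init__(self):
        for blk, size in BLOCK_SIZES.items():
            arr = np.asarray(getattr(self, "gamma" + blk), dtype=float)
            if arr.shape != (size,):
                raise ValueError(f"gamma{blk} must have length {size}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"gamma{blk} must be finite")
            setattr(self, "gamma" + blk, arr)

    def block(self, name: str) -> np.ndarray:
        return getattr(self, "gamma" + name)

    def replace_block(self, name: str, values) -> "VitalRateCoefficients":
        kw = {("gamma" + b): self.block(b).copy() for b in BLOCK_SIZES}
        kw["gamma" + name] = np.asarray(values, dtype=float)
        return VitalRateCoefficients(**kw)

    def to_dict(self) -> dict:
        return {
            f"gamma{blk}_{i + 1}": float(v)
            for blk in BLOCK_SIZES
            for i, v in enumerate(self.block(blk))
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRateCoefficients":
        kw = {}
        for blk, size in BLOCK_SIZES.items():
            kw["gamma" + blk] = np.array(
                [d[f"gamma{blk}_{i + 1}"] for i in range(size)], dtype=float
            )
        return cls(**kw)


@dataclass
class PredationConfig:
    """Fixed predation-risk parameters (tuned, not estimated).

    ``rho_*`` are wet-season predation risks per class; the dry-season risk
    is ``dry_multiplier`` times the wet-season risk; adult male survival is
    ``male_survival_factor`` times adult female survival.
    """

    rho_r: float = 0.10
    rho_q: float = 0.05
    rho_h: float = 0.03
    rho_a: float = 0.02
    dry_multiplier: float = 0.7
    male_survival_factor: float = 0.997

    def __post_init__(self):
        for name in ("rho_r", "rho_q", "rho_h", "rho_a"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("dry_multiplier", "male_survival_factor"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def to_dict(self) -> dict:
        return {
            "rho_r": self.rho_r, "rho_q": self.rho_q,
            "rho_h": self.rho_h, "rho_a": self.rho_a,
            "dry_multiplier": self.dry_multiplier,
            "male_survival_factor": self.male_survival_factor,
        }


@dataclass
class VitalRates:
    """Realized monthly rates; fields are scalars or aligned arrays."""

    r: np.ndarray
    s_q: np.ndarray
    s_h: np.ndarray
    s_a_f: np.ndarray
    s_a_m: np.ndarray
    phi: np.ndarray

    def at(self, i: int) -> "VitalRates":
        return VitalRates(*(np.asarray(getattr(self, f))[..., i]
                            for f in ("r", "s_q", "s_h", "s_a_f", "s_a_m", "phi")))


def natural_rates(coeffs: VitalRateCoefficients, table: CovariateTable):
    """Predation-free rates (r~, S~q, S~h, S~a, phi) for every table row."""
    out = []
    for blk in ("R", "Q", "H", "A", "S"):
        X = table.design_matrix(blk)
        g = coeffs.block(blk)
        if X.shape[1] != g.shape[0]:
            raise ValueError(
                f"design block {blk} has {X.shape[1]} columns but gamma{blk} "
                f"has {g.shape[0]} entries"
            )
        out.append(inverse_logit(X @ g))
    return tuple(out)


def realized_rates(
    natural, cfg: PredationConfig, months
) -> VitalRates:
    """Apply the predation factorization and male-survival adjustment.

    ``natural`` is the (r~, S~q, S~h, S~a, phi) tuple; ``months`` are the
    calendar months (1..12) aligned with the rate arrays.
    """
    r_nat, sq_nat, sh_nat, sa_nat, phi = (np.asarray(a, dtype=float) for a in natural)
    months = np.asarray(months)
    mult = np.where(np.isin(months, list(DRY_MONTHS)), cfg.dry_multiplier, 1.0)
    r = _clamp(r_nat * (1.0 - cfg.rho_r * mult))
    s_q = _clamp(sq_nat * (1.0 - cfg.rho_q * mult))
    s_h = _clamp(sh_nat * (1.0 - cfg.rho_h * mult))
    s_a_f = _clamp(sa_nat * (1.0 - cfg.rho_a * mult))
    s_a_m = _clamp(cfg.male_survival_factor * s_a_f)
    return VitalRates(r=r, s_q=s_q, s_h=s_h, s_a_f=s_a_f, s_a_m=s_a_m,
                      phi=_clamp(phi * np.ones_like(mult)))


def rates_table(
    coeffs: VitalRateCoefficients, table: CovariateTable, cfg: PredationConfig
) -> VitalRates:
    """Realized rates for every row of the covariate table."""
    nat = natural_rates(coeffs, table)
    months = table.df["month"].to_numpy().astype(int)
    return realized_rates(nat, cfg, months)
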