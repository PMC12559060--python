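"""Model validation machinery: balanced bootstrap, Jolly's ratio estimator,
hypothetical ground-series generation, coverage, and the predation scan.

The validation loop mirrors the design of the motivating study: resample
transect-level aerial survey units with a balanced bootstrap, re-estimate the
ecosystem total of every survey with Jolly's Method 2 for unequal transects,
treat each bootstrap series as the truth of a hypothetical population,
generate matching ground-count series, refit the model to each (cheaply, by
importance-resampling from a reference chain), and score how often the
bootstrap totals fall inside the refitted 95% credible limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariates import MONTH0_DEFAULT, month_of
from .observation import VarianceParams, counts_from_classes


@dataclass
class TransectSurvey:
    """One aerial survey: sampled (unit_id, area km^2, count) transect units."""

    month_index: int
    units: list  # of (unit_id, area, count)
    total_area: float  # frame area Z in km^2
    n_frame: float | None = None  # population units in the frame

    def __post_init__(self):
        areas = np.array([u[1] for u in self.units], dtype=float)
        counts = np.array([u[2] for u in self.units], dtype=float)
        if np.any(areas <= 0):
            raise ValueError("unit areas must be positive")
        if np.any(counts < 0):
            raise ValueError("unit counts must be non-negative")
        if areas.sum() > self.total_area + 1e-9:
            raise ValueError("sampled area exceeds the frame area")
        if self.n_frame is None:
            # Jolly's convention when the frame size is not supplied
            self.n_frame = self.total_area / areas.mean()

    @property
    def areas(self) -> np.ndarray:
        return np.array([u[1] for u in self.units], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array([u[2] for u in self.units], dtype=float)


@dataclass
class BootstrapSeries:
    """Per-survey Jolly estimates of one bootstrap replicate."""

    replicate: int
    months: np.ndarray
    estimates: np.ndarray
    variances: np.ndarray

    def __post_init__(self):
        if np.any(self.estimates < 0):
            raise ValueError("bootstrap totals must be non-negative")


def balanced_bootstrap(n: int, n_reps: int, rng) -> list[np.ndarray]:
    """Balanced bootstrap index lists: each unit appears exactly n_reps times.

    Concatenate ``n_reps`` copies of 0..n-1, permute uniformly, and split
    into ``n_reps`` blocks of size n (within-block repeats allowed).
    """
    if n < 1 or n_reps < 1:
        raise ValueError("n and n_reps must be positive")
    pool = np.tile(np.arange(n), n_reps)
    rng.shuffle(pool)
    return [pool[b * n:(b + 1) * n].copy() for b in range(n_reps)]


def jolly_method2(areas, counts, Z: float, n_frame: float):
    """Jolly's Method 2 ratio estimator for transects of unequal area.

    R = sum(y)/sum(z); estimate = Z*R;
    Var = N(N - n)/n * (s_y^2 - 2 R s_zy + R^2 s_z^2) with sample variances
    and covariance of counts y and areas z, floored at zero.
    """
    z = np.asarray(areas, dtype=float)
    y = np.asarray(counts, dtype=float)
    n = len(z)
    if n < 1 or z.sum() <= 0:
        raise ValueError("need at least one unit with positive area")
    R = y.sum() / z.sum()
    est = Z * R
    if n < 2:
        return est, np.nan
    s_y = np.var(y, ddof=1)
    s_z = np.var(z, ddof=1)
    s_zy = np.cov(z, y, ddof=1)[0, 1]
    var = n_frame * (n_frame - n) / n * (s_y - 2.0 * R * s_zy + R * R * s_z)
    return float(est), float(max(var, 0.0))


def bootstrap_population_series(
    surveys: list[TransectSurvey], n_boot: int, seed: int
) -> list[BootstrapSeries]:
    """Balanced-bootstrap + Jolly re-estimation across a list of surveys.

    The b-th resample of every survey is paired into the b-th series.
    """
    if not surveys:
        raise ValueError("need at least one survey")
    rng = np.random.default_rng(seed)
    months = np.array([s.month_index for s in surveys])
    est = np.zeros((n_boot, len(surveys)))
    var = np.zeros((n_boot, len(surveys)))
    for j, s in enumerate(surveys):
        z, y = s.areas, s.counts
        idx_lists = balanced_bootstrap(len(z), n_boot, rng)
        for b, idx in enumerate(idx_lists):
            est[b, j], var[b, j] = jolly_method2(z[idx], y[idx], s.total_area,
                                                 s.n_frame)
    return [
        BootstrapSeries(replicate=b, months=months.copy(),
                        estimates=est[b], variances=var[b])
        for b in range(n_boot)
    ]


def observed_class_profile(ground: np.ndarray) -> np.ndarray:
    """(T, 5) observed class shares per survey month.

    Allocating hypothetical totals with the observed per-month composition
    keeps the generated class series demographically coherent (a fixed
    calendar profile is not the realization of any cohort process, and a
    refit then has to absorb the incoherence into its observation
    variances).
    """
    g = np.asarray(ground, dtype=float)
    tot = np.maximum(g.sum(axis=1, keepdims=True), 1.0)
    out = g / tot
    # guard months with an all-zero row
    zero = out.sum(axis=1) == 0
    out[zero] = 0.2
    return out


def monthly_class_proportions(ground: np.ndarray,
                              month0: int = MONTH0_DEFAULT) -> np.ndarray:
    """(12, 5) average observed class shares by calendar month."""
    T = ground.shape[0]
    months = np.asarray(month_of(np.arange(1, T + 1), month0))
    out = np.zeros((12, 5))
    for m in range(1, 13):
        sel = ground[months == m].astype(float)
        shares = sel / np.maximum(sel.sum(axis=1, keepdims=True), 1.0)
        out[m - 1] = shares.mean(axis=0)
        out[m - 1] /= out[m - 1].sum()
    return out


def generate_hypothetical_ground_series(
    series: BootstrapSeries,
    class_proportions: np.ndarray,
    v: VarianceParams,
    K: float,
    T: int,
    seed: int,
    month0: int = MONTH0_DEFAULT,
) -> np.ndarray:
    """Ground-count series (T, 5) of a hypothetical population.

    The bootstrap ecosystem totals are interpolated to a monthly series,
    scaled down to the reserve by 1/K, allocated to the five classes with
    multinomial jitter around the monthly proportion profile, and pushed
    through the gamma-Poisson observation layer.

    ``class_proportions`` is either a (12, 5) calendar profile or a (T, 5)
    per-month profile (e.g. :func:`observed_class_profile` of a reference
    series, which keeps the generated composition demographically coherent).
    """
    rng = np.random.default_rng(seed)
    ts = np.arange(1, T + 1)
    totals = np.interp(ts, series.months, series.estimates)
    reserve = totals / K
    props = np.asarray(class_proportions, dtype=float)
    months = np.asarray(month_of(ts, month0))
    out = np.zeros((T, 5), dtype=np.int64)
    for i, t in enumerate(ts):
        tot = int(round(reserve[i]))
        if tot <= 0:
            continue
        p = props[i] if props.shape[0] == T else props[months[i] - 1]
        classes = rng.multinomial(tot, p / p.sum())
        out[i] = counts_from_classes(classes, v, rng).as_array()
    return out


def interpolated_truth(series: BootstrapSeries, T: int) -> np.ndarray:
    """The hypothetical population's monthly ecosystem totals (length T)."""
    ts = np.arange(1, T + 1)
    return np.interp(ts, series.months, series.estimates)


def credible_coverage(truth, lo, hi) -> float:
    """Percent of time points where lo <= truth <= hi."""
    truth = np.asarray(truth, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if not (truth.shape == lo.shape == hi.shape):
        raise ValueError("truth, lo, hi must have equal length")
    return 100.0 * float(np.mean((lo <= truth) & (truth <= hi)))


def predation_sensitivity_scan(
    coeffs,
    predation,
    covtab,
    init_state,
    target_class: str,
    multipliers,
    T: int,
    n_reps: int,
    seed: int,
):
    """Mean total-population trajectories under scaled predation risk.

    ``target_class`` is one of 'r', 'q', 'h', 'a'; each multiplier scales
    that class's baseline risk, the population is forward-simulated
    ``n_reps`` times, and the mean reserve total B(t) curve is returned per
    multiplier, shape (len(multipliers), T + 1).
    """
    from dataclasses import replace as _replace

    from .states import StateVector, simulate_transition
    from .vitalrates import rates_table

    if target_class not in ("r", "q", "h", "a"):
        raise ValueError("target_class must be one of 'r', 'q', 'h', 'a'")
    multipliers = list(multipliers)
    if any(m < 0 for m in multipliers):
        raise ValueError("multipliers must be non-negative")
    out = np.zeros((len(multipliers), T + 1))
    for i, mult in enumerate(multipliers):
        cfg = _replace(predation,
                       **{f"rho_{target_class}":
                          min(getattr(predation, f"rho_{target_class}") * mult,
                              0.999)})
        rates = rates_table(coeffs, covtab, cfg)
        rng = np.random.default_rng(seed)
        acc = np.zeros(T + 1)
        for _ in range(n_reps):
            Y = StateVector(init_state.y.copy())
            acc[0] += Y.B
            for t in range(1, T + 1):
                Y = simulate_transition(Y, rates.at(t), rng)
                acc[t] += Y.B
        out[i] = acc / n_reps
    return out
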