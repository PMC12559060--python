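"""Per-month covariate construction for the vital-rate regressions.

Covariates are built on a 0-based internal month index *t*, where t = 0 is
the month immediately before the first ground-survey month (a June in the
motivating study, so t = 1 is July).  Climate history must extend far enough
back to supply the deepest lagged covariate (the lag-1 annual seasonal total
needs 23 pre-study months).

Lag convention: lag ``j`` means the value at ``t - j``; the 7-11-month
rainfall window before a birth month corresponds to lags 6..10 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONTH0_DEFAULT = 6  # calendar month (June) of internal index t = 0
DRY_MONTHS = frozenset({7, 8, 9, 10})

#: calendar season windows: name -> (first calendar month, length in months)
SEASONS = {
    "earlywet": (11, 4),  # Nov-Feb
    "latewet": (3, 4),    # Mar-Jun
    "earlydry": (7, 2),   # Jul-Aug
    "latedry": (9, 2),    # Sep-Oct
    "wet": (11, 8),       # Nov-Jun
    "dry": (7, 4),        # Jul-Oct
    "annual": (11, 12),   # Nov-Oct
}

#: columns of the covariate table that are z-scored when standardize is set
CONTINUOUS_COLUMNS = (
    "month_c", "month_sq", "month_cu",
    "rain_7_11", "rain_7_11_sq",
    "Npop", "Apop",
    "mintemp", "maxtemp", "lagmin2", "lagmax1",
    "lagrain0", "lagrain4", "lagrain5", "lagrain6", "lagrain7",
    "wet1", "dry1", "earlywet1", "mavrain_3_4",
)


class MissingHistoryError(ValueError):
    """A lagged covariate reaches back before the available history."""


def month_of(t, month0: int = MONTH0_DEFAULT):
    """Calendar month (1..12) of internal month index ``t``."""
    return (np.asarray(t) + month0 - 1) % 12 + 1


def season_of(t, month0: int = MONTH0_DEFAULT):
    """Season code: 1 = wet (Nov-Jun), 2 = dry (Jul-Oct)."""
    m = month_of(t, month0)
    return np.where(np.isin(m, list(DRY_MONTHS)), 2, 1)


@dataclass(frozen=True)
class MonthlySeries:
    """A contiguous monthly series ``values[i]`` at index ``start + i``."""

    start: int
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("MonthlySeries needs a non-empty 1-D array")

    @property
    def end(self) -> int:
        """Last covered month index (inclusive)."""
        return self.start + self.values.size - 1

    def at(self, t: int) -> float:
        if t < self.start or t > self.end:
            raise MissingHistoryError(
                f"month {t} outside available history [{self.start}, {self.end}]"
            )
        return float(self.values[t - self.start])


@dataclass(frozen=True)
class ClimateSeries:
    """Monthly rainfall (mm) and min/max temperature (deg C)."""

    rain: MonthlySeries
    tmin: MonthlySeries
    tmax: MonthlySeries
    month0: int = MONTH0_DEFAULT

    def __post_init__(self):
        if not (self.rain.start == self.tmin.start == self.tmax.start):
            raise ValueError("climate series must share a start index")
        if not (self.rain.values.size == self.tmin.values.size == self.tmax.values.size):
            raise ValueError("climate series must share a length")
        if np.any(self.rain.values < 0):
            raise ValueError("rainfall must be non-negative")
        if np.any(self.tmin.values > self.tmax.values):
            raise ValueError("tmin must not exceed tmax")

    @property
    def history_start(self) -> int:
        return self.rain.start


@dataclass(frozen=True)
class PopulationSeries:
    """Monthly population index (animals), e.g. interpolated aerial totals."""

    total: MonthlySeries

    def __post_init__(self):
        if np.any(self.total.values < 0):
            raise ValueError("population totals must be non-negative")


def lag_value(x: MonthlySeries, t: int, j: int) -> float:
    """Value of ``x`` at lag ``j``: x(t - j); j = 0 is the current month."""
    if t - j < x.start:
        raise MissingHistoryError(
            f"lag {j} at month {t} needs history from month {t - j}; "
            f"earliest usable t is {x.start + j}"
        )
    return x.at(t - j)


def moving_average_lags(x: MonthlySeries, t: int, j_lo: int, j_hi: int) -> float:
    """Arithmetic mean of x(t-j) for j = j_lo..j_hi inclusive."""
    if j_lo > j_hi:
        raise ValueError("j_lo must not exceed j_hi")
    vals = [lag_value(x, t, j) for j in range(j_lo, j_hi + 1)]
    return float(np.mean(vals))


def seasonal_total_lag1(
    x: MonthlySeries, t: int, season: str, month0: int = MONTH0_DEFAULT
) -> float:
    """Total of ``x`` over the most recent complete named season before ``t``.

    The window is the latest full calendar window of the season that ends
    strictly before month ``t`` (the season "in the immediately preceding
    year").
    """
    try:
        start_month, length = SEASONS[season]
    except KeyError:
        raise ValueError(f"unknown season {season!r}; one of {sorted(SEASONS)}") from None
    end_month = (start_month - 1 + length - 1) % 12 + 1
    # latest e < t with calendar month == end_month
    e = t - 1 - int((month_of(t - 1, month0) - end_month) % 12)
    window = range(e - length + 1, e + 1)
    if window[0] < x.start:
        raise MissingHistoryError(
            f"season {season!r} before month {t} needs months "
            f"{window[0]}..{e}; history starts at {x.start}"
        )
    return float(sum(x.at(u) for u in window))


def monthly_population_series(aerial, t_range) -> PopulationSeries:
    """Linearly interpolate sparse aerial totals onto a monthly index.

    ``aerial`` is a sequence of objects with ``month_index`` and ``psi``
    attributes (or (month, total) pairs).  Extrapolation outside the survey
    span is constant at the nearest survey value.
    """
    pts = []
    for a in aerial:
        if hasattr(a, "month_index"):
            pts.append((int(a.month_index), float(a.psi)))
        else:
            pts.append((int(a[0]), float(a[1])))
    if not pts:
        raise ValueError("need at least one aerial observation")
    pts.sort()
    months = np.array([p[0] for p in pts], dtype=float)
    totals = np.array([p[1] for p in pts], dtype=float)
    ts = np.asarray(list(t_range), dtype=int)
    interp = np.interp(ts, months, totals)
    return PopulationSeries(MonthlySeries(int(ts[0]), interp))


@dataclass
class CovariateTable:
    """One row per modelled month, plus the z-scoring constants.

    ``df`` is indexed by the internal month index.  ``scaling`` maps each
    standardized column to its (mean, sd) so fitted coefficients can be
    back-transformed to the raw covariate scale.
    """

    df: pd.DataFrame
    month0: int = MONTH0_DEFAULT
    scaling: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.df)

    @property
    def t_index(self) -> np.ndarray:
        return self.df.index.to_numpy()

    def month_dummies(self) -> np.ndarray:
        m = self.df["month"].to_numpy()
        return (m[:, None] == np.arange(1, 13)[None, :]).astype(float)

    def season_dummies(self) -> np.ndarray:
        s = self.df["season"].to_numpy()
        return np.column_stack([(s == 1).astype(float), (s == 2).astype(float)])

    def design_matrix(self, block: str) -> np.ndarray:
        """Regression design for one vital-rate block ('R','Q','H','A','S')."""
        d = self.df
        if block == "R":
            cols = ["month_c", "month_sq", "month_cu", "rain_7_11",
                    "rain_7_11_sq", "Npop", "mintemp", "maxtemp"]
            return np.column_stack(
                [np.ones(len(d))] + [d[c].to_numpy() for c in cols]
            )
        if block == "Q":
            return np.column_stack(
                [self.month_dummies(), d["dry1"].to_numpy(), d["mavrain_3_4"].to_numpy()]
            )
        if block == "H":
            return np.column_stack([self.month_dummies(), d["earlywet1"].to_numpy()])
        if block == "A":
            cols = ["Apop", "lagrain4", "lagrain5", "lagrain6", "lagrain7", "wet1"]
            return np.column_stack(
                [self.season_dummies()] + [d[c].to_numpy() for c in cols]
            )
        if block == "S":
            cols = ["wet1", "dry1", "lagrain0", "rain_7_11",
                    "mintemp", "lagmin2", "lagmax1"]
            return np.column_stack(
                [self.season_dummies()] + [d[c].to_numpy() for c in cols]
            )
        raise ValueError(f"unknown design block {block!r}")


def build_covariate_table(
    climate: ClimateSeries,
    pop: PopulationSeries,
    t_range,
    standardize: bool = True,
) -> CovariateTable:
    """Assemble the covariate table for every month of ``t_range``."""
    ts = [int(t) for t in t_range]
    month0 = climate.month0
    rows = {}
    missing: dict[str, str] = {}

    def col(name, fn):
        try:
            rows[name] = np.array([fn(t) for t in ts], dtype=float)
        except MissingHistoryError as e:  # collect, report all at once
            missing[name] = str(e)

    m = np.asarray(month_of(np.array(ts), month0), dtype=int)
    rows["month"] = m.astype(float)
    rows["season"] = np.asarray(season_of(np.array(ts), month0), dtype=float)
    rows["month_c"] = m.astype(float)
    rows["month_sq"] = m.astype(float) ** 2
    rows["month_cu"] = m.astype(float) ** 3

    rain, tmin, tmax = climate.rain, climate.tmin, climate.tmax
    col("rain_7_11", lambda t: moving_average_lags(rain, t, 6, 10))
    col("Npop", lambda t: lag_value(pop.total, t, 7))
    col("Apop", lambda t: lag_value(pop.total, t, 1))
    col("mintemp", lambda t: lag_value(tmin, t, 0))
    col("maxtemp", lambda t: lag_value(tmax, t, 0))
    col("lagmin2", lambda t: lag_value(tmin, t, 2))
    col("lagmax1", lambda t: lag_value(tmax, t, 1))
    for j in (0, 4, 5, 6, 7):
        col(f"lagrain{j}", lambda t, j=j: lag_value(rain, t, j))
    col("wet1", lambda t: seasonal_total_lag1(rain, t, "wet", month0))
    col("dry1", lambda t: seasonal_total_lag1(rain, t, "dry", month0))
    col("earlywet1", lambda t: seasonal_total_lag1(rain, t, "earlywet", month0))
    col("mavrain_3_4", lambda t: moving_average_lags(rain, t, 3, 4))

    if missing:
        raise MissingHistoryError(
            "insufficient climate/population history for columns: "
            + "; ".join(f"{k} ({v})" for k, v in sorted(missing.items()))
        )

    if "rain_7_11" in rows:
        rows["rain_7_11_sq"] = rows["rain_7_11"] ** 2

    df = pd.DataFrame(rows, index=pd.Index(ts, name="t"))
    scaling = {}
    if standardize:
        for c in CONTINUOUS_COLUMNS:
            mu = float(df[c].mean())
            sd = float(df[c].std(ddof=0))
            if sd == 0.0:
                sd = 1.0
            df[c] = (df[c] - mu) / sd
            scaling[c] = (mu, sd)
    return CovariateTable(df=df, month0=month0, scaling=scaling)
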