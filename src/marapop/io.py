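"""File formats, configuration loading and run manifests.

CSV dialects (UTF-8, header row, '.' decimal, dates as YYYY-MM, all dates
first-of-month):

* climate:   date, rain_mm, tmin_c, tmax_c
* ground:    date, n, q, h, f, m
* aerial:    date, estimate, se
* transects: survey_date, unit_id, area_km2, count

Internally months are 0-based indices with t = 0 the month before the first
ground-survey month (the June-1989 analogue).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import ClimateSeries, MonthlySeries
from .observation import AerialObservation
from .validation import TransectSurvey


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _parse_month(s: str, what: str, row: int):
    try:
        return datetime.strptime(str(s).strip(), "%Y-%m")
    except ValueError:
        raise SchemaError(
            f"{what} table row {row}: date {s!r} is not YYYY-MM"
        ) from None


def _month_number(d: datetime) -> int:
    return d.year * 12 + (d.month - 1)


def _check_contiguous(dates, what: str):
    nums = [_month_number(d) for d in dates]
    for i in range(1, len(nums)):
        if nums[i] != nums[i - 1] + 1:
            gap = datetime(
                (nums[i - 1] + 1) // 12, (nums[i - 1] + 1) % 12 + 1, 1
            )
            raise SchemaError(
                f"{what} table has a month gap: missing {gap:%Y-%m}"
            )


def read_climate_csv(path, t0_date: str, month0: int | None = None) -> ClimateSeries:
    """Read a climate CSV; ``t0_date`` (YYYY-MM) anchors internal index 0."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "rain_mm", "tmin_c", "tmax_c"], "climate")
    dates = [_parse_month(s, "climate", i) for i, s in enumerate(df["date"])]
    _check_contiguous(dates, "climate")
    t0 = _parse_month(t0_date, "anchor", 0)
    start = _month_number(dates[0]) - _month_number(t0)
    if month0 is None:
        month0 = t0.month
    return ClimateSeries(
        rain=MonthlySeries(start, df["rain_mm"].to_numpy(float)),
        tmin=MonthlySeries(start, df["tmin_c"].to_numpy(float)),
        tmax=MonthlySeries(start, df["tmax_c"].to_numpy(float)),
        month0=month0,
    )


def write_climate_csv(path, climate: ClimateSeries, t0_date: str):
    t0 = _parse_month(t0_date, "anchor", 0)
    n0 = _month_number(t0)
    rows = []
    for i in range(climate.rain.values.size):
        num = n0 + climate.rain.start + i
        rows.append(
            {
                "date": f"{num // 12:04d}-{num % 12 + 1:02d}",
                "rain_mm": climate.rain.values[i],
                "tmin_c": climate.tmin.values[i],
                "tmax_c": climate.tmax.values[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ground_csv(path, t0_date: str) -> np.ndarray:
    """Ground counts as a (T, 5) array for months 1..T after the anchor."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "n", "q", "h", "f", "m"], "ground")
    dates = [_parse_month(s, "ground", i) for i, s in enumerate(df["date"])]
    _check_contiguous(dates, "ground")
    t0 = _parse_month(t0_date, "anchor", 0)
    first = _month_number(dates[0]) - _month_number(t0)
    if first != 1:
        raise SchemaError(
            f"ground table must start one month after the anchor {t0_date}; "
            f"it starts at offset {first}"
        )
    counts = df[["n", "q", "h", "f", "m"]].to_numpy()
    for i, row in enumerate(counts):
        if np.any(row < 0):
            raise SchemaError(f"ground table row {i}: negative count")
    return counts.astype(np.int64)


def write_ground_csv(path, ground: np.ndarray, t0_date: str):
    t0 = _parse_month(t0_date, "anchor", 0)
    n0 = _month_number(t0)
    rows = []
    for i, row in enumerate(np.asarray(ground)):
        num = n0 + 1 + i
        rows.append(
            dict(
                date=f"{num // 12:04d}-{num % 12 + 1:02d}",
                n=int(row[0]), q=int(row[1]), h=int(row[2]),
                f=int(row[3]), m=int(row[4]),
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aerial_csv(path, t0_date: str) -> list[AerialObservation]:
    df = pd.read_csv(path)
    _require_columns(df, ["date", "estimate", "se"], "aerial")
    t0 = _parse_month(t0_date, "anchor", 0)
    out = []
    for i, row in df.iterrows():
        d = _parse_month(row["date"], "aerial", int(i))
        t = _month_number(d) - _month_number(t0)
        if row["estimate"] < 0:
            raise SchemaError(f"aerial table row {i}: negative estimate")
        out.append(
            AerialObservation(month_index=t, psi=float(row["estimate"]),
                              se=float(row["se"]))
        )
    return out


def write_aerial_csv(path, aerial, t0_date: str):
    t0 = _parse_month(t0_date, "anchor", 0)
    n0 = _month_number(t0)
    rows = []
    for a in aerial:
        num = n0 + a.month_index
        rows.append(
            dict(date=f"{num // 12:04d}-{num % 12 + 1:02d}",
                 estimate=a.psi, se=a.se)
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transects_csv(path, t0_date: str) -> list[TransectSurvey]:
    df = pd.read_csv(path)
    _require_columns(df, ["survey_date", "unit_id", "area_km2", "count"],
                     "transects")
    t0 = _parse_month(t0_date, "anchor", 0)
    surveys = []
    for date, grp in df.groupby("survey_date", sort=True):
        d = _parse_month(date, "transects", 0)
        t = _month_number(d) - _month_number(t0)
        units = [
            (str(r["unit_id"]), float(r["area_km2"]), int(r["count"]))
            for _, r in grp.iterrows()
        ]
        total_area = float(grp.attrs.get("total_area", 0.0)) or sum(
            u[1] for u in units
        )
        surveys.append(
            TransectSurvey(month_index=t, units=units, total_area=total_area)
        )
    return surveys


def write_transects_csv(path, surveys, t0_date: str):
    t0 = _parse_month(t0_date, "anchor", 0)
    n0 = _month_number(t0)
    rows = []
    for s in surveys:
        num = n0 + s.month_index
        date = f"{num // 12:04d}-{num % 12 + 1:02d}"
        for uid, area, count in s.units:
            rows.append(dict(survey_date=date, unit_id=uid,
                             area_km2=area, count=count))
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------- configuration ------------------------------------


def save_coefficients(path, coeffs):
    """Write vital-rate coefficients as named YAML (gammaR_1, ...)."""
    with open(path, "w") as fh:
        yaml.safe_dump(coeffs.to_dict(), fh, sort_keys=True)


def load_coefficients(path):
    from .vitalrates import VitalRateCoefficients

    with open(path) as fh:
        d = yaml.safe_load(fh)
    return VitalRateCoefficients.from_dict(d)


def load_config(path, cls):
    """Load a YAML file into a config dataclass, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a mapping")
    import dataclasses

    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise SchemaError(
            f"config {path} has unknown key(s): {', '.join(sorted(unknown))}"
        )
    return cls(**raw)


def save_config(path, cfg):
    import dataclasses

    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(clean(d), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Provenance record written next to every stochastic output."""

    command: str
    seed: int
    outputs: list = field(default_factory=list)
    config_path: str | None = None
    config_sha256: str | None = None
    package_version: str = "0.1.0"
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def create(cls, command: str, seed: int, outputs, config_path=None):
        sha = None
        if config_path is not None:
            sha = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        return cls(command=command, seed=seed, outputs=[str(o) for o in outputs],
                   config_path=str(config_path) if config_path else None,
                   config_sha256=sha)

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
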