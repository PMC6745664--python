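"""Calendar-indexed daily series, catchment descriptors, units, and CSV I/O.

Everything downstream (the bucket simulator, event statistics, scenario
engine) consumes :class:`DailySeries`: a contiguous run of calendar days with
one value slot per day.  Missing observations are explicit ``NaN`` markers,
never skipped dates, so gap handling is a property of each statistic rather
than of the storage layer.

Streamflow lives in two unit systems: areally normalised ``mm/day`` for
water-balance arithmetic and ``L/s`` for the ecological thresholds, with the
catchment area carrying the conversion.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Recognised unit tags for :class:`DailySeries`.
MM_PER_DAY = "mm/day"
LITRES_PER_SECOND = "L/s"
DEG_C = "degC"
MM = "mm"
KNOWN_UNITS = frozenset({MM_PER_DAY, LITRES_PER_SECOND, DEG_C, MM})

#: L/s produced by 1 mm/day over 1 km**2 (1e6 L per mm*km**2, 86400 s/day).
LS_PER_MMDAY_KM2 = 1e6 / 86400.0

COVER_NAMES = ("holm_oak", "beech", "heathland")


class FormatError(ValueError):
    """A data file violates the documented layout."""


class UnitsError(ValueError):
    """Series units are missing, unknown, or inconsistent with an operation."""


# ---------------------------------------------------------------------------
# DailySeries


@dataclass
class DailySeries:
    """A contiguous daily time series starting at ``start``.

    Parameters
    ----------
    start:
        Calendar date of the first value.
    values:
        One value per day; ``NaN`` marks a missing observation.
    units:
        One of :data:`KNOWN_UNITS`.
    """

    start: dt.date
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("DailySeries values must be one-dimensional")
        if len(self.values) < 1:
            raise ValueError("DailySeries must hold at least one day")
        if self.units not in KNOWN_UNITS:
            raise UnitsError(f"unknown units {self.units!r}; expected one of {sorted(KNOWN_UNITS)}")
        if not isinstance(self.start, dt.date) or isinstance(self.start, dt.datetime):
            # accept datetime.date only; normalise datetimes defensively
            if isinstance(self.start, dt.datetime):
                self.start = self.start.date()
            else:
                raise TypeError("start must be a datetime.date")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> dt.date:
        return self.start + dt.timedelta(days=len(self) - 1)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self), freq="D")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, ``True`` on non-missing days."""
        return ~np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def completeness(self) -> float:
        """Fraction of days with a value, in [0, 1]."""
        return 1.0 - self.n_missing / len(self)

    def months(self) -> np.ndarray:
        """Calendar month (1-12) of each day."""
        return self.dates.month.to_numpy()

    def date_of(self, i: int) -> dt.date:
        return self.start + dt.timedelta(days=int(i))

    def with_values(self, values: np.ndarray, units: str | None = None) -> "DailySeries":
        return DailySeries(self.start, np.asarray(values, dtype=float), units or self.units)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values}, index=self.dates)


def check_aligned(a: DailySeries, b: DailySeries) -> None:
    """Raise unless two series cover exactly the same calendar days."""
    if a.start != b.start or len(a) != len(b):
        raise ValueError(
            f"series are misaligned: {a.start}..{a.end} (n={len(a)}) vs "
            f"{b.start}..{b.end} (n={len(b)})"
        )


@dataclass
class ClimateForcing:
    """Gap-free daily temperature (degC) and precipitation (mm) driving a run."""

    temperature: DailySeries
    precipitation: DailySeries

    def __post_init__(self) -> None:
        if self.temperature.units != DEG_C:
            raise UnitsError("forcing temperature must be in degC")
        if self.precipitation.units != MM:
            raise UnitsError("forcing precipitation must be in mm")
        check_aligned(self.temperature, self.precipitation)

    def __len__(self) -> int:
        return len(self.temperature)

    @property
    def start(self) -> dt.date:
        return self.temperature.start


# ---------------------------------------------------------------------------
# Catchment descriptor


@dataclass
class CatchmentSpec:
    """Catchment area and landscape-cover fractions.

    Fractions are of catchment area, must each lie in [0, 1] and sum to one
    within 1e-9.  The canonical covers for the Montseny reference catchment
    are ``holm_oak``, ``beech`` and ``heathland``.
    """

    area_km2: float
    cover_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.area_km2 > 0:
            raise ValueError("catchment area must be positive")
        fr = dict(self.cover_fractions)
        for name, f in fr.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"cover fraction {name}={f} outside [0, 1]")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cover fractions sum to {total!r}, not 1")
        self.cover_fractions = fr

    def with_covers(self, fractions: Mapping[str, float]) -> "CatchmentSpec":
        return CatchmentSpec(self.area_km2, dict(fractions))


def montseny_reference_catchment() -> CatchmentSpec:
    """The 2 km**2 Montseny reference catchment with present-day covers."""
    return CatchmentSpec(2.0, {"holm_oak": 0.522, "beech": 0.151, "heathland": 0.327})


# ---------------------------------------------------------------------------
# Unit conversion


def _check_flow(q, what: str) -> np.ndarray:
    arr = np.asarray(q, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError(f"negative {what} is not a physical streamflow")
    return arr


def mmday_to_ls(q, area_km2: float):
    """Convert areally normalised streamflow (mm/day) to discharge (L/s).

    ``q`` may be a scalar or array; NaN (missing) passes through.
    """
    if not area_km2 > 0:
        raise ValueError("area must be positive")
    arr = _check_flow(q, "streamflow")
    out = arr * (area_km2 * LS_PER_MMDAY_KM2)
    return float(out) if np.isscalar(q) else out


def ls_to_mmday(q, area_km2: float):
    """Inverse of :func:`mmday_to_ls`; round-trips to 1e-12 relative."""
    if not area_km2 > 0:
        raise ValueError("area must be positive")
    arr = _check_flow(q, "discharge")
    out = arr / (area_km2 * LS_PER_MMDAY_KM2)
    return float(out) if np.isscalar(q) else out


def convert_flow_series(series: DailySeries, units: str, area_km2: float) -> DailySeries:
    """Return ``series`` expressed in ``units`` (mm/day or L/s)."""
    if units not in (MM_PER_DAY, LITRES_PER_SECOND):
        raise UnitsError(f"cannot convert a flow series to {units!r}")
    if series.units == units:
        return series
    if series.units == MM_PER_DAY and units == LITRES_PER_SECOND:
        return series.with_values(mmday_to_ls(series.values, area_km2), units)
    if series.units == LITRES_PER_SECOND and units == MM_PER_DAY:
        return series.with_values(ls_to_mmday(series.values, area_km2), units)
    raise UnitsError(f"cannot convert {series.units!r} to {units!r}")


# ---------------------------------------------------------------------------
# Seasons


class Season(NamedTuple):
    dry: bool          # hydrological dry season, April-September
    name: str          # meteorological season: winter/spring/summer/autumn


_MET_SEASON = {12: "winter", 1: "winter", 2: "winter",
               3: "spring", 4: "spring", 5: "spring",
               6: "summer", 7: "summer", 8: "summer",
               9: "autumn", 10: "autumn", 11: "autumn"}

SEASON_NAMES = ("winter", "spring", "summer", "autumn")


def season_of(date: dt.date) -> Season:
    """Dry/wet flag (dry = Apr 1 - Sep 30) and meteorological season (DJF...)."""
    return Season(dry=4 <= date.month <= 9, name=_MET_SEASON[date.month])


def dry_season_mask(months: np.ndarray) -> np.ndarray:
    """Vectorised dry-season membership from calendar months."""
    return (months >= 4) & (months <= 9)


# ---------------------------------------------------------------------------
# CSV I/O


def read_daily_csv(path, units: str) -> DailySeries:
    """Read a ``date,value`` CSV into a contiguous :class:`DailySeries`.

    Dates are ISO-8601; an empty value field marks a missing day.  Calendar
    gaps between listed dates are filled with missing markers.  Duplicate or
    unparseable rows raise :class:`FormatError` naming the offending line.
    """
    rows: dict[dt.date, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header[:2]] != ["date", "value"]:
            raise FormatError(f"{path}: line 1: expected header 'date,value', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected two fields, got {row!r}")
            try:
                date = dt.date.fromisoformat(row[0].strip())
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: unparseable date {row[0]!r}") from None
            raw = row[1].strip()
            if raw == "":
                value = np.nan
            else:
                try:
                    value = float(raw)
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: unparseable value {row[1]!r}"
                    ) from None
            if date in rows:
                raise FormatError(f"{path}: line {lineno}: duplicate date {date.isoformat()}")
            rows[date] = value
    if not rows:
        raise FormatError(f"{path}: no data rows")
    first, last = min(rows), max(rows)
    n = (last - first).days + 1
    values = np.full(n, np.nan)
    for date, value in rows.items():
        values[(date - first).days] = value
    series = DailySeries(first, values, units)
    if series.n_missing:
        log.info("%s: %d of %d days missing (completeness %.1f%%)",
                 path, series.n_missing, n, 100 * series.completeness)
    return series


def write_daily_csv(series: DailySeries, path) -> None:
    """Write a series as ``date,value`` CSV; missing days get an empty field."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "value"])
        for i, v in enumerate(series.values):
            writer.writerow([series.date_of(i).isoformat(), "" if np.isnan(v) else repr(float(v))])


# ---------------------------------------------------------------------------
# Reporting helpers


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up, the convention used for printed table cells.

    Binary ``round()`` would turn e.g. 7.55 into 7.5; published hydrological
    tables round half away from zero.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
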