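"""Ecological flow-threshold statistics.

Two kinds of events matter for stream-dwelling amphibians in these
headwaters: days when discharge drops below a low-flow threshold ``Q_low``
(downstream reaches lose surface flow) and single-day spates, identified
through the day-over-day flow increase ``Q_diff`` exceeding its 99th
percentile (catastrophic-drift risk).  This module computes day counts,
consecutive-day event durations, flow-duration curves, seasonal breakdowns,
the robustness of conclusions to the choice of ``Q_low``, and the
precipitation-streamflow lag.

Conventions (applied uniformly):

* strict inequalities for "below" and "above" comparisons;
* a missing day breaks a consecutive-day run and invalidates both
  ``Q_diff`` values it touches;
* a ``Q_diff`` value belongs to the dry season if its *later* day falls in
  April-September (the increase manifests on that day);
* percentiles use linear interpolation between order statistics
  (rank ``1 + p*(n-1)``).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .series import (
    LITRES_PER_SECOND,
    MM_PER_DAY,
    DailySeries,
    SEASON_NAMES,
    UnitsError,
    check_aligned,
    convert_flow_series,
    dry_season_mask,
    season_of,
)

log = logging.getLogger(__name__)

#: Event-duration histogram bin edges (days): <7, 7-30, 31-90, >90.
DURATION_BINS = ((1, 6), (7, 30), (31, 90), (91, None))

DEFAULT_ROBUSTNESS_THRESHOLDS = (2.0, 1.0, 0.5, 0.25, 0.2)


@dataclass
class ThresholdSpec:
    """Ecological flow thresholds (L/s) and the area tying them to mm/day.

    Defaults are the Montseny reference-catchment values: surface flow is
    lost below 0.33 L/s, and the 99th-percentile day-over-day increases of
    the observed record are 97 L/s (whole year) and 42 L/s (dry season).
    """

    q_low: float = 0.33
    qdiff_all: float = 97.0
    qdiff_dry: float = 42.0
    percentile: float = 0.99
    area_km2: float = 2.0

    def __post_init__(self) -> None:
        if min(self.q_low, self.qdiff_all, self.qdiff_dry) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.percentile < 1.0:
            raise ValueError("percentile must lie in (0, 1)")
        if not self.area_km2 > 0:
            raise ValueError("area must be positive")


@dataclass
class EventSummary:
    """Threshold-event counts for one simulated or observed record."""

    days_below: int
    events_below: int
    event_durations: list[int]
    events_above_all: int
    events_above_dry: int
    annual_q: float                      # mm/year
    seasonal_days_below: dict[str, int]
    n_days: int

    def __post_init__(self) -> None:
        if sum(self.event_durations) != self.days_below:
            raise ValueError("event durations must partition days_below")
        if self.events_below > self.days_below:
            raise ValueError("cannot have more events than days")
        if self.annual_q < 0:
            raise ValueError("annual flow must be >= 0")

    @property
    def fraction_below(self) -> float:
        """Fraction of (non-missing) days spent below the low-flow threshold."""
        return self.days_below / self.n_days

    def duration_histogram(self) -> dict[str, int]:
        return duration_histogram(self.event_durations)


# ---------------------------------------------------------------------------
# Q_diff


def qdiff_series(q: DailySeries) -> DailySeries:
    """Day-over-day flow difference, ``q(t) - q(t-1)``, in L/s.

    Defined only where both days are observed; one day shorter than the
    input, starting on the input's second day.
    """
    if q.units != LITRES_PER_SECOND:
        raise UnitsError("qdiff_series expects L/s; convert with convert_flow_series")
    if len(q) < 2:
        raise ValueError("need at least two days to difference")
    diff = np.diff(q.values)  # NaN propagates from either endpoint
    return DailySeries(q.start + dt.timedelta(days=1), diff, LITRES_PER_SECOND)


def percentile_threshold(values: np.ndarray, p: float = 0.99) -> float:
    """Empirical percentile with linear interpolation (rank ``1 + p*(n-1)``)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 10:
        raise ValueError(f"need >= 10 non-missing values, got {len(arr)}")
    return float(np.percentile(arr, 100.0 * p))


def dry_season_qdiff(qdiff: DailySeries) -> np.ndarray:
    """Q_diff values whose later day falls in the dry season (Apr-Sep)."""
    return qdiff.values[dry_season_mask(qdiff.months())]


# ---------------------------------------------------------------------------
# Threshold counting


def count_days_below(q: DailySeries, threshold: float) -> int:
    """Days with flow strictly below ``threshold``; missing days excluded."""
    v = q.values
    return int(np.sum(v[~np.isnan(v)] < threshold))


def events_below(q: DailySeries, threshold: float) -> list[tuple[dt.date, int]]:
    """Maximal runs of consecutive below-threshold days.

    Returns ``(start_date, duration_days)`` per event.  A missing day
    terminates a run: an unobserved day cannot attest continuity.
    """
    below = q.values < threshold  # NaN compares False, breaking runs
    events: list[tuple[dt.date, int]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            events.append((q.date_of(start), i - start))
            start = None
    if start is not None:
        events.append((q.date_of(start), len(below) - start))
    return events


def duration_histogram(durations: Sequence[int]) -> dict[str, int]:
    """Histogram of event durations into the <7 / 7-30 / 31-90 / >90 day bins."""
    out: dict[str, int] = {}
    for lo, hi in DURATION_BINS:
        label = f">{lo - 1}" if hi is None else (f"<{hi + 1}" if lo == 1 else f"{lo}-{hi}")
        out[label] = sum(1 for d in durations if d >= lo and (hi is None or d <= hi))
    return out


def count_single_day_events_above(qdiff: DailySeries, threshold: float,
                                  dry_only: bool = False) -> int:
    """Days with flow increase strictly above ``threshold``.

    Every exceedance is an independent single-day event, whether or not it
    neighbours another one.  ``dry_only`` restricts to dry-season days
    (membership by the later day of the pair).
    """
    v = dry_season_qdiff(qdiff) if dry_only else qdiff.values
    return int(np.sum(v[~np.isnan(v)] > threshold))


# ---------------------------------------------------------------------------
# Flow-duration curve


def flow_duration_curve(q: DailySeries) -> pd.DataFrame:
    """Flow against percent of time exceeded (Weibull plotting positions).

    Rank ``i`` of ``n`` sorted-descending flows plots at ``100*i/(n+1)``.
    """
    v = q.values[~np.isnan(q.values)]
    if len(v) < 1:
        raise ValueError("flow-duration curve needs at least one observed day")
    flows = np.sort(v)[::-1]
    ranks = np.arange(1, len(flows) + 1)
    return pd.DataFrame(
        {"exceedance_percent": 100.0 * ranks / (len(flows) + 1), "flow": flows}
    )


# ---------------------------------------------------------------------------
# Seasonal breakdown and record summary


def seasonal_days_below(q: DailySeries, threshold: float) -> dict[str, int]:
    """Days below threshold per meteorological season (DJF/MAM/JJA/SON)."""
    months = q.months()
    v = q.values
    out = {s: 0 for s in SEASON_NAMES}
    ok = ~np.isnan(v)
    for i in np.flatnonzero(ok & (v < threshold)):
        out[season_of(q.date_of(int(i))).name] += 1
    return out


def annual_flow(q: DailySeries) -> float:
    """Mean flow scaled to mm/year (365.25-day year), over observed days."""
    if q.units != MM_PER_DAY:
        raise UnitsError("annual_flow expects mm/day")
    v = q.values[~np.isnan(q.values)]
    if len(v) == 0:
        raise ValueError("no observed days")
    return float(v.mean() * 365.25)


def summarize_events(q_mmday: DailySeries, thresholds: ThresholdSpec) -> EventSummary:
    """Full :class:`EventSummary` of a streamflow record (mm/day input)."""
    q_ls = convert_flow_series(q_mmday, LITRES_PER_SECOND, thresholds.area_km2)
    qd = qdiff_series(q_ls)
    events = events_below(q_ls, thresholds.q_low)
    durations = [d for _, d in events]
    return EventSummary(
        days_below=count_days_below(q_ls, thresholds.q_low),
        events_below=len(events),
        event_durations=durations,
        events_above_all=count_single_day_events_above(qd, thresholds.qdiff_all),
        events_above_dry=count_single_day_events_above(qd, thresholds.qdiff_dry, dry_only=True),
        annual_q=annual_flow(q_mmday),
        seasonal_days_below=seasonal_days_below(q_ls, thresholds.q_low),
        n_days=int(q_ls.mask.sum()),
    )


def thresholds_from_record(q_obs_mmday: DailySeries, area_km2: float,
                           q_low: float = 0.33, percentile: float = 0.99) -> ThresholdSpec:
    """Derive spate thresholds from an observed record's Q_diff percentiles."""
    q_ls = convert_flow_series(q_obs_mmday, LITRES_PER_SECOND, area_km2)
    qd = qdiff_series(q_ls)
    return ThresholdSpec(
        q_low=q_low,
        qdiff_all=percentile_threshold(qd.values, percentile),
        qdiff_dry=percentile_threshold(dry_season_qdiff(qd), percentile),
        percentile=percentile,
        area_km2=area_km2,
    )


# ---------------------------------------------------------------------------
# Threshold robustness


def day_counts_table(
    q_by_scenario: Mapping[str, DailySeries],
    thresholds: Sequence[float] = (2.0, 1.0, 0.5, 0.33, 0.25, 0.2),
) -> pd.DataFrame:
    """Days below each candidate Q_low (columns) per scenario (rows), L/s input."""
    data = {
        name: [count_days_below(q, thr) for thr in thresholds]
        for name, q in q_by_scenario.items()
    }
    return pd.DataFrame(data, index=list(thresholds)).T


def threshold_robustness(
    day_counts: pd.DataFrame,
    reference_threshold: float = 0.33,
    alternative_thresholds: Sequence[float] = DEFAULT_ROBUSTNESS_THRESHOLDS,
) -> pd.Series:
    """Correlation of alternative-threshold day counts with the reference.

    ``day_counts`` has one row per scenario, one column per threshold.  The
    product-moment correlation with the ``reference_threshold`` column is
    reported per alternative; a constant vector yields NaN (undefined).
    """
    if len(day_counts) < 3:
        raise ValueError("need at least 3 scenarios to correlate across")
    ref = day_counts[reference_threshold].to_numpy(dtype=float)
    out = {}
    for thr in alternative_thresholds:
        alt = day_counts[thr].to_numpy(dtype=float)
        if np.ptp(ref) == 0 or np.ptp(alt) == 0:
            log.warning("constant day-count vector at threshold %s; correlation undefined", thr)
            out[thr] = np.nan
        else:
            out[thr] = float(np.corrcoef(ref, alt)[0, 1])
    return pd.Series(out, name="r_vs_reference")


# ---------------------------------------------------------------------------
# Precipitation-streamflow lag


def best_lag(p: DailySeries, q: DailySeries, max_lag: int = 10) -> int:
    """Lag k maximising corr(P(t), Q(t+k)) on pairwise-complete days.

    Ties break to the smallest lag; lags with fewer than 3 complete pairs
    are skipped and logged.
    """
    check_aligned(p, q)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    pv, qv = p.values, q.values
    best_k, best_r = None, -np.inf
    for k in range(max_lag + 1):
        a = pv[: len(pv) - k]
        b = qv[k:]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
            log.info("lag %d skipped: insufficient overlap or constant series", k)
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        if r > best_r:
            best_k, best_r = k, r
    if best_k is None:
        raise ValueError("no lag had enough pairwise-complete data")
    return best_k
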