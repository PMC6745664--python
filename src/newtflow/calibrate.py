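"""Performance metrics and Monte-Carlo calibration of the bucket model.

Four "hard" criteria score a simulation against observations on
pairwise-complete days (gaps in the observed record are simply excluded):

* Nash-Sutcliffe efficiency (NS) — weighs high flows;
* NS on log-transformed flows (log-NS) — weighs low flows;
* relative volume difference (RVD, %) — cumulative bias;
* observed/simulated variance ratio (VAR) — guards against over-smooth
  simulations.

"Soft" criteria penalise mismatches in ecological event counts (days below
Q_low, single-day spates above the Q_diff thresholds).  A single weighted
composite turns all of this into a total order over candidate parameter
sets, which the Monte-Carlo scheme needs for automated selection: uniform
sampling within ranges, iterated with ranges shrinking toward the elite of
all samples scored so far.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .buckets import ParameterSet, _run_units
from .events import ThresholdSpec, dry_season_mask
from .series import (
    LS_PER_MMDAY_KM2,
    CatchmentSpec,
    ClimateForcing,
    DailySeries,
    check_aligned,
)

log = logging.getLogger(__name__)

SOFT_KEYS = ("q_low_days", "qdiff_all_events", "qdiff_dry_events")

DEFAULT_WEIGHTS = {
    "rvd": 1.0,
    "var": 1.0,
    "q_low_days": 0.5,
    "qdiff_all_events": 0.5,
    "qdiff_dry_events": 0.5,
}

#: Offset (mm/day) added before the log transform; strictly positive and
#: below the mm/day equivalent of the 0.33 L/s low-flow threshold.
DEFAULT_LOG_OFFSET = 0.01


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for these inputs (e.g. constant obs)."""


def _pairwise(obs: DailySeries, sim: DailySeries) -> tuple[np.ndarray, np.ndarray]:
    check_aligned(obs, sim)
    ok = obs.mask & sim.mask
    if ok.sum() < 2:
        raise UndefinedMetricError("need at least 2 pairwise-complete days")
    return obs.values[ok], sim.values[ok]


def nash_sutcliffe(obs: DailySeries, sim: DailySeries) -> float:
    """NS = 1 - SSE / SS(obs about its mean); 1 is a perfect fit."""
    o, s = _pairwise(obs, sim)
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0.0:
        raise UndefinedMetricError("NS undefined: constant observations")
    return 1.0 - float(np.sum((o - s) ** 2)) / denom


def log_nash_sutcliffe(obs: DailySeries, sim: DailySeries,
                       offset: float = DEFAULT_LOG_OFFSET) -> float:
    """NS on ln(flow + offset); the offset admits zero-flow days."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    o, s = _pairwise(obs, sim)
    lo, ls_ = np.log(o + offset), np.log(s + offset)
    denom = float(np.sum((lo - lo.mean()) ** 2))
    if denom == 0.0:
        raise UndefinedMetricError("log-NS undefined: constant observations")
    return 1.0 - float(np.sum((lo - ls_) ** 2)) / denom


def relative_volume_difference(obs: DailySeries, sim: DailySeries) -> float:
    """Percent bias of cumulative simulated vs observed volume."""
    o, s = _pairwise(obs, sim)
    total = float(o.sum())
    if total <= 0:
        raise UndefinedMetricError("RVD undefined: zero observed volume")
    return 100.0 * (float(s.sum()) - total) / total


def variance_ratio(obs: DailySeries, sim: DailySeries) -> float:
    """var(obs) / var(sim), sample variances (n-1 denominator)."""
    o, s = _pairwise(obs, sim)
    vs = float(np.var(s, ddof=1))
    if vs == 0.0:
        raise UndefinedMetricError("variance ratio undefined: constant simulation")
    vo = float(np.var(o, ddof=1))
    if vo == 0.0:
        raise UndefinedMetricError("variance ratio undefined: constant observations")
    return vo / vs


@dataclass
class PerformanceMetrics:
    ns: float
    log_ns: float
    rvd: float
    var_ratio: float
    soft_penalties: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {"ns": self.ns, "log_ns": self.log_ns, "rvd": self.rvd,
               "var_ratio": self.var_ratio}
        out.update({k: float(v) for k, v in self.soft_penalties.items()})
        return out


def _event_counts(values_ls: np.ndarray, months: np.ndarray,
                  thresholds: ThresholdSpec) -> dict[str, int]:
    """Day/event counts on an L/s array (NaN-aware), for soft penalties."""
    ok = ~np.isnan(values_ls)
    below = int(np.sum(values_ls[ok] < thresholds.q_low))
    diff = values_ls[1:] - values_ls[:-1]
    dok = ~np.isnan(diff)
    above_all = int(np.sum(diff[dok] > thresholds.qdiff_all))
    dry = dry_season_mask(months[1:]) & dok
    above_dry = int(np.sum(diff[dry] > thresholds.qdiff_dry))
    return {"q_low_days": below, "qdiff_all_events": above_all,
            "qdiff_dry_events": above_dry}


def compute_metrics(obs: DailySeries, sim: DailySeries,
                    thresholds: ThresholdSpec | None = None,
                    log_offset: float = DEFAULT_LOG_OFFSET) -> PerformanceMetrics:
    """All hard metrics, plus soft event-count penalties when thresholds given."""
    soft: dict[str, int] = {}
    if thresholds is not None:
        factor = thresholds.area_km2 * LS_PER_MMDAY_KM2
        months = obs.months()
        co = _event_counts(obs.values * factor, months, thresholds)
        cs = _event_counts(sim.values * factor, months, thresholds)
        soft = {k: abs(cs[k] - co[k]) for k in SOFT_KEYS}
    return PerformanceMetrics(
        ns=nash_sutcliffe(obs, sim),
        log_ns=log_nash_sutcliffe(obs, sim, log_offset),
        rvd=relative_volume_difference(obs, sim),
        var_ratio=variance_ratio(obs, sim),
        soft_penalties=soft,
    )


def composite_objective(metrics: PerformanceMetrics,
                        weights: Mapping[str, float] | None = None,
                        observed_counts: Mapping[str, int] | None = None) -> float:
    """Single scalar ranking candidate parameter sets; higher is better.

    ``ns + log_ns - w_rvd*|RVD|/100 - w_var*|1 - VAR| - sum soft terms``,
    each soft penalty normalised by the observed count (floored at 1).
    A perfect fit with no penalties scores 2.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    obj = (metrics.ns + metrics.log_ns
           - w["rvd"] * abs(metrics.rvd) / 100.0
           - w["var"] * abs(1.0 - metrics.var_ratio))
    for key, pen in metrics.soft_penalties.items():
        norm = max(1, int(observed_counts[key])) if observed_counts else 1
        obj -= w.get(key, 0.5) * pen / norm
    return float(obj)


#: Plausible sampling ranges per parameter kind, used by default_parameter_ranges.
_RANGE_BY_FIELD = {
    "tau_quick": (1.0, 3.0),
    "tau_soil": (1.0, 10.0),
    "tau_gw": (5.0, 60.0),
    "field_capacity": (50.0, 300.0),
    "soil_to_gw_fraction": (0.0, 1.0),
    "et_degreeday": (0.05, 0.5),
    "et_temp_threshold": (-2.0, 4.0),
    "et_adjustment": (0.0, 3.0),
    "melt_degreeday": (1.0, 6.0),
    "snow_temp_threshold": (-2.0, 2.0),
}


def default_parameter_ranges() -> dict[str, tuple[float, float]]:
    """Uniform sampling ranges for the full 28-parameter calibration vector."""
    return {
        name: _RANGE_BY_FIELD[name.split(".", 1)[1]]
        for name in ParameterSet.parameter_names()
    }


# ---------------------------------------------------------------------------
# Monte-Carlo calibration


@dataclass
class CalibrationResult:
    """Outcome of the iterated Monte-Carlo search.

    ``top_sets`` holds one (parameters, metrics, objective) triple per
    iteration — each iteration's champion — sorted by objective, best first.
    """

    best_set: ParameterSet
    best_metrics: PerformanceMetrics
    best_objective: float
    top_sets: list[tuple[ParameterSet, PerformanceMetrics, float]]
    parameter_names: tuple[str, ...]
    initial_ranges: dict[str, tuple[float, float]]
    final_ranges: dict[str, tuple[float, float]]
    seed: int

    def top_values(self) -> np.ndarray:
        """(n_iterations, n_parameters) array of the iteration-best vectors."""
        return np.stack([ps.to_vector(self.parameter_names) for ps, _, _ in self.top_sets])


ELITE_FRACTION = 0.05
RANGE_INFLATION = 0.10


def monte_carlo_calibrate(
    obs: DailySeries,
    forcing: ClimateForcing,
    catchment: CatchmentSpec,
    ranges: Mapping[str, tuple[float, float]],
    iterations: int = 100,
    runs_per_iteration: int = 1000,
    seed: int = 0,
    base_params: ParameterSet | None = None,
    thresholds: ThresholdSpec | None = None,
    weights: Mapping[str, float] | None = None,
    spinup_days: int = 365,
    log_offset: float = DEFAULT_LOG_OFFSET,
    snow: bool = True,
) -> CalibrationResult:
    """Iterated uniform Monte-Carlo search over ``ranges``.

    Each iteration draws ``runs_per_iteration`` parameter vectors uniformly
    within the current ranges, simulates, and scores with the composite
    objective.  Between iterations the ranges shrink to the min-max envelope
    of the running elite — the best ``5% x runs_per_iteration`` samples
    scored so far — inflated by 10% and clipped to the initial ranges.
    Fully reproducible from ``seed``; a failing sample scores ``-inf`` and
    is logged, never fatal.

    The observation window must equal the forcing window minus spin-up.
    """
    if iterations < 1 or runs_per_iteration < 1:
        raise ValueError("iterations and runs_per_iteration must be >= 1")
    names = tuple(ranges)
    lo0 = np.array([ranges[n][0] for n in names], dtype=float)
    hi0 = np.array([ranges[n][1] for n in names], dtype=float)
    if np.any(lo0 >= hi0):
        bad = [n for n, l, h in zip(names, lo0, hi0) if l >= h]
        raise ValueError(f"invalid ranges (low >= high) for {bad}")
    if len(forcing) != spinup_days + len(obs):
        raise ValueError("forcing must cover spin-up plus the observation window")

    base = base_params or ParameterSet()
    rng = np.random.default_rng(seed)

    # Pre-extract everything the scoring loop needs.
    T = forcing.temperature.values
    P = forcing.precipitation.values
    unit_names = list(catchment.cover_fractions)
    fractions = np.array([catchment.cover_fractions[u] for u in unit_names])
    init = np.stack([base.storage_of(u).as_array() for u in unit_names])
    base_prm = np.stack([base.units[u].as_array() for u in unit_names])
    base_snow = float(base.snow_temp_threshold)

    from .buckets import UNIT_PARAM_FIELDS  # local import avoids cycle at top

    # map sampled names to (unit_row, field_col) or the global snow slot
    slots: list[tuple[int, int]] = []
    for n in names:
        scope, pname = n.split(".", 1)
        if scope == "global":
            slots.append((-1, 0))
        else:
            slots.append((unit_names.index(scope), UNIT_PARAM_FIELDS.index(pname)))

    ok = obs.mask
    o = obs.values[ok]
    if len(o) < 2 or np.ptp(o) == 0:
        raise UndefinedMetricError("observations constant or too short to calibrate")
    o_mean_ss = float(np.sum((o - o.mean()) ** 2))
    lo_obs = np.log(o + log_offset)
    lo_ss = float(np.sum((lo_obs - lo_obs.mean()) ** 2))
    o_sum = float(o.sum())
    o_var = float(np.var(o, ddof=1))
    months = obs.months()
    obs_counts = None
    factor = None
    if thresholds is not None:
        factor = thresholds.area_km2 * LS_PER_MMDAY_KM2
        obs_counts = _event_counts(obs.values * factor, months, thresholds)
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)

    def score(q_mm: np.ndarray) -> tuple[float, PerformanceMetrics]:
        s = q_mm[ok]
        ns = 1.0 - float(np.sum((o - s) ** 2)) / o_mean_ss
        ls_ = np.log(s + log_offset)
        log_ns = 1.0 - float(np.sum((lo_obs - ls_) ** 2)) / lo_ss
        rvd = 100.0 * (float(s.sum()) - o_sum) / o_sum
        s_var = float(np.var(s, ddof=1))
        var_ratio = o_var / s_var if s_var > 0 else np.inf
        soft: dict[str, int] = {}
        obj = ns + log_ns - w["rvd"] * abs(rvd) / 100.0 - w["var"] * abs(1.0 - var_ratio)
        if thresholds is not None:
            cs = _event_counts(q_mm * factor, months, thresholds)
            for key in SOFT_KEYS:
                pen = abs(cs[key] - obs_counts[key])
                soft[key] = pen
                obj -= w.get(key, 0.5) * pen / max(1, obs_counts[key])
        return obj, PerformanceMetrics(ns, log_ns, rvd, var_ratio, soft)

    cur_lo, cur_hi = lo0.copy(), hi0.copy()
    pool_x: list[np.ndarray] = []
    pool_s: list[np.ndarray] = []
    iteration_best: list[tuple[np.ndarray, PerformanceMetrics, float]] = []

    for it in range(iterations):
        X = rng.uniform(cur_lo, cur_hi, size=(runs_per_iteration, len(names)))
        scores = np.full(runs_per_iteration, -np.inf)
        best_in_iter: tuple[np.ndarray, PerformanceMetrics, float] | None = None
        for r in range(runs_per_iteration):
            prm = base_prm.copy()
            snow_thr = base_snow
            for (row, col), v in zip(slots, X[r]):
                if row < 0:
                    snow_thr = float(v)
                else:
                    prm[row, col] = v
            # clamp residence times to the stability floor
            prm[:, 0:3] = np.maximum(prm[:, 0:3], 1.0)
            try:
                q_u, _aet, _st, _cq, _ca = _run_units(T, P, prm, snow_thr, init, snow)
                q_mm = (fractions @ q_u)[spinup_days:]
                obj, metrics = score(q_mm)
                if not math.isfinite(obj):
                    raise FloatingPointError("non-finite objective")
            except Exception as exc:  # noqa: BLE001 - a bad sample must not abort
                log.warning("iteration %d run %d failed (%s); scored -inf", it, r, exc)
                continue
            scores[r] = obj
            if best_in_iter is None or obj > best_in_iter[2]:
                best_in_iter = (X[r].copy(), metrics, obj)
        if best_in_iter is None:
            raise RuntimeError(f"every sample of iteration {it} failed")
        iteration_best.append(best_in_iter)
        pool_x.append(X)
        pool_s.append(scores)

        all_x = np.concatenate(pool_x)
        all_s = np.concatenate(pool_s)
        n_elite = max(1, int(np.ceil(ELITE_FRACTION * runs_per_iteration)))
        elite = all_x[np.argsort(all_s)[::-1][:n_elite]]
        env_lo, env_hi = elite.min(axis=0), elite.max(axis=0)
        pad = (RANGE_INFLATION / 2.0) * (env_hi - env_lo)
        cur_lo = np.maximum(env_lo - pad, lo0)
        cur_hi = np.minimum(env_hi + pad, hi0)
        degenerate = cur_hi <= cur_lo
        if degenerate.any():  # keep a sliver of width so sampling stays valid
            width = 1e-9 * np.maximum(1.0, np.abs(cur_lo))
            cur_hi = np.where(degenerate, cur_lo + width, cur_hi)

    order = sorted(range(len(iteration_best)), key=lambda i: -iteration_best[i][2])
    top_sets = [
        (base.replace_from_vector(names, iteration_best[i][0]),
         iteration_best[i][1], iteration_best[i][2])
        for i in order
    ]
    best_set, best_metrics, best_obj = top_sets[0]
    return CalibrationResult(
        best_set=best_set,
        best_metrics=best_metrics,
        best_objective=best_obj,
        top_sets=top_sets,
        parameter_names=names,
        initial_ranges={n: (float(l), float(h)) for n, l, h in zip(names, lo0, hi0)},
        final_ranges={n: (float(l), float(h)) for n, l, h in zip(names, cur_lo, cur_hi)},
        seed=seed,
    )
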