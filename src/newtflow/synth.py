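"""Seeded generators for Mediterranean forcing, future deltas, and truth runs.

The weather generator emulates the statistical structure of subhumid
Mediterranean daily forcing: a seasonal temperature sinusoid with AR(1)
noise, and a two-state (wet/dry) first-order occurrence chain with monthly
parameters and gamma-distributed wet-day amounts — mild winters, wet
springs and autumns, dry summers.  Default parameters target the study
area's climatology (mean annual temperature 11.5 degC, annual
precipitation 983 mm); gamma scales are derived from the annual total, so
the analytic expectation matches by construction.

Future forcings are built by the delta-change method (monthly temperature
shifts, monthly precipitation factors), with presets whose annual-mean
changes match the downscaled projections for the region (+1.3 / +1.3 /
+1.8 / +3.9 degC and -11 / -16 / -17 / -28 % precipitation for
RCP4.5-near, RCP8.5-near, RCP4.5-far, RCP8.5-far) and whose precipitation
cuts are deeper in the already dry summer months.

``generate_truth_run`` produces a synthetic "observed" record from the
bucket model itself — multiplicative lognormal noise, gaps in a few
contiguous blocks mimicking instrument outages — for parameter-recovery
and end-to-end testing without any external dataset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .buckets import CatchmentSpec, ParameterSet, SimulationResult, simulate
from .series import DEG_C, MM, MM_PER_DAY, ClimateForcing, DailySeries

_MONTH_DAYS = np.array([31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# Monthly shares of annual precipitation (normalised below): wet spring and
# autumn, a marked October maximum, dry July-August.
_P_SHARE_RAW = np.array([58, 52, 72, 88, 96, 55, 22, 40, 90, 115, 92, 65], dtype=float)
DEFAULT_P_FRACTION = tuple(_P_SHARE_RAW / _P_SHARE_RAW.sum())

DEFAULT_WET_PROB = (0.26, 0.24, 0.28, 0.32, 0.33, 0.24, 0.12, 0.16, 0.27, 0.32, 0.30, 0.27)
DEFAULT_WET_AFTER_WET = (0.50, 0.48, 0.52, 0.55, 0.56, 0.48, 0.35, 0.38, 0.52, 0.56, 0.54, 0.51)
DEFAULT_GAMMA_SHAPE = (0.7,) * 12


@dataclass
class WeatherConfig:
    """Parameters of the daily weather generator (all monthly arrays Jan-Dec)."""

    mean_annual_t: float = 11.5          # degC
    t_amplitude: float = 7.5             # degC, seasonal sinusoid semi-amplitude
    t_ar1: float = 0.65                  # lag-1 autocorrelation of T anomalies
    t_noise_sd: float = 1.8              # stationary sd of T anomalies, degC
    annual_p: float = 983.0              # mm, expected annual total
    wet_prob: tuple = DEFAULT_WET_PROB   # stationary wet-day probability
    wet_after_wet: tuple = DEFAULT_WET_AFTER_WET
    gamma_shape: tuple = DEFAULT_GAMMA_SHAPE
    monthly_p_fraction: tuple = DEFAULT_P_FRACTION
    gamma_scale: tuple | None = None     # derived from annual_p when None

    def __post_init__(self) -> None:
        for name in ("wet_prob", "wet_after_wet"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,) or np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must be 12 probabilities in [0, 1]")
        if not -1 < self.t_ar1 < 1:
            raise ValueError("t_ar1 must lie in (-1, 1)")
        if self.t_noise_sd < 0 or self.t_amplitude < 0:
            raise ValueError("temperature amplitude and noise sd must be >= 0")
        shape = np.asarray(self.gamma_shape, dtype=float)
        if shape.shape != (12,) or np.any(shape <= 0):
            raise ValueError("gamma_shape must be 12 positive values")
        frac = np.asarray(self.monthly_p_fraction, dtype=float)
        if frac.shape != (12,) or np.any(frac < 0) or abs(frac.sum() - 1) > 1e-9:
            raise ValueError("monthly_p_fraction must be 12 non-negative values summing to 1")
        if self.gamma_scale is None:
            wet = np.asarray(self.wet_prob, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                mean_amount = np.where(
                    wet > 0, self.annual_p * frac / (_MONTH_DAYS * wet), 0.0
                )
            self.gamma_scale = tuple(np.where(shape > 0, mean_amount / shape, 0.0))
        scale = np.asarray(self.gamma_scale, dtype=float)
        if scale.shape != (12,) or np.any(scale < 0):
            raise ValueError("gamma_scale must be 12 non-negative values")
        expected = expected_annual_precipitation(self)
        if self.annual_p > 0 and abs(expected - self.annual_p) > 0.05 * self.annual_p:
            raise ValueError(
                f"analytic annual precipitation {expected:.0f} mm deviates more "
                f"than 5% from annual_p={self.annual_p:.0f} mm"
            )


def expected_annual_precipitation(config: WeatherConfig) -> float:
    """Analytic E[annual P] = sum over months of days * wet_prob * gamma mean."""
    wet = np.asarray(config.wet_prob, dtype=float)
    shape = np.asarray(config.gamma_shape, dtype=float)
    scale = np.asarray(config.gamma_scale, dtype=float)
    return float(np.sum(_MONTH_DAYS * wet * shape * scale))


def generate_weather(
    config: WeatherConfig,
    years: int,
    seed: int = 0,
    start_year: int = 1981,
) -> ClimateForcing:
    """Generate ``years`` calendar years of daily temperature and precipitation.

    Temperature is a seasonal sinusoid (peak in late July) plus AR(1)
    anomalies; precipitation occurrence follows the monthly two-state chain
    with gamma amounts on wet days.  Bit-reproducible from ``seed``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    start = dt.date(start_year, 1, 1)
    dates = pd.date_range(start, dt.date(start_year + years - 1, 12, 31), freq="D")
    n = len(dates)
    month = dates.month.to_numpy() - 1
    doy = dates.dayofyear.to_numpy()

    rng = np.random.default_rng(seed)

    # temperature
    seasonal = config.mean_annual_t + config.t_amplitude * np.sin(
        2 * np.pi * (doy - 110) / 365.25
    )
    eps_sd = config.t_noise_sd * np.sqrt(1 - config.t_ar1**2)
    eps = rng.normal(0.0, eps_sd, n)
    anom = np.empty(n)
    prev = rng.normal(0.0, config.t_noise_sd) if config.t_noise_sd > 0 else 0.0
    for i in range(n):
        prev = config.t_ar1 * prev + eps[i]
        anom[i] = prev
    T = seasonal + anom

    # precipitation occurrence chain
    pi = np.asarray(config.wet_prob, dtype=float)
    p11 = np.asarray(config.wet_after_wet, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p01 = np.where(pi < 1, pi * (1 - p11) / (1 - pi), 1.0)
    p01 = np.clip(p01, 0.0, 1.0)
    u = rng.uniform(size=n)
    wet = np.zeros(n, dtype=bool)
    prev_wet = u[0] < pi[month[0]]
    wet[0] = prev_wet
    for i in range(1, n):
        p = p11[month[i]] if prev_wet else p01[month[i]]
        prev_wet = u[i] < p
        wet[i] = prev_wet

    shape = np.asarray(config.gamma_shape, dtype=float)[month]
    scale = np.asarray(config.gamma_scale, dtype=float)[month]
    amounts = rng.gamma(np.where(shape > 0, shape, 1.0), np.where(scale > 0, scale, 1.0), n)
    P = np.where(wet & (scale > 0), amounts, 0.0)

    return ClimateForcing(
        temperature=DailySeries(start, T, DEG_C),
        precipitation=DailySeries(start, P, MM),
    )


# ---------------------------------------------------------------------------
# Delta change


@dataclass
class DeltaChange:
    """Monthly temperature shifts (degC) and precipitation factors (>= 0)."""

    dt_monthly: tuple
    p_factor_monthly: tuple

    def __post_init__(self) -> None:
        for name in ("dt_monthly", "p_factor_monthly"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
        if np.any(np.asarray(self.p_factor_monthly) < 0):
            raise ValueError("precipitation factors must be >= 0")

    def inverse(self) -> "DeltaChange":
        factors = np.asarray(self.p_factor_monthly, dtype=float)
        if np.any(factors == 0):
            raise ValueError("cannot invert a zero precipitation factor")
        return DeltaChange(
            tuple(-np.asarray(self.dt_monthly, dtype=float)),
            tuple(1.0 / factors),
        )


def apply_delta_change(forcing: ClimateForcing, delta: DeltaChange) -> ClimateForcing:
    """Shift temperature and scale precipitation by monthly deltas."""
    month = forcing.temperature.months() - 1
    dtm = np.asarray(delta.dt_monthly, dtype=float)
    fm = np.asarray(delta.p_factor_monthly, dtype=float)
    return ClimateForcing(
        temperature=forcing.temperature.with_values(forcing.temperature.values + dtm[month]),
        precipitation=forcing.precipitation.with_values(
            forcing.precipitation.values * fm[month]
        ),
    )


# zero-mean monthly shapes of the warming signal: milder winter/spring and
# stronger summer/autumn near term, flatter far term
_DT_SHAPE_NEAR = np.array([-0.25, -0.25, -0.15, -0.15, -0.05, 0.15,
                           0.25, 0.30, 0.35, 0.30, -0.20, -0.30])
_DT_SHAPE_FAR = np.array([-0.15, -0.15, -0.05, 0.0, 0.0, 0.10,
                          0.15, 0.15, 0.05, 0.0, -0.05, -0.05])
# relative shape of the precipitation reduction: concentrated in summer
_P_REDUCTION_SHAPE = np.array([0.0, 0.1, 0.3, 0.6, 0.8, 1.3, 1.6, 1.5, 1.0, 0.5, 0.3, 0.1])

#: (annual mean warming degC, annual fractional precipitation decrease)
PRESET_TARGETS = {
    "rcp45_near": (1.3, 0.11),
    "rcp85_near": (1.3, 0.16),
    "rcp45_far": (1.8, 0.17),
    "rcp85_far": (3.9, 0.28),
}


def delta_change_preset(name: str) -> DeltaChange:
    """Preset monthly delta-change profile for an emulated pathway/period.

    The temperature profile's simple monthly mean equals the annual target
    exactly; precipitation factors are scaled so the annual reduction
    matches the target when weighted by the default monthly climatology,
    with summer months cut hardest.
    """
    try:
        warm, reduction = PRESET_TARGETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_TARGETS)}"
        ) from None
    shape = _DT_SHAPE_FAR if name.endswith("_far") else _DT_SHAPE_NEAR
    dtm = warm + shape - shape.mean()     # exact zero-mean correction
    w = np.asarray(DEFAULT_P_FRACTION)
    lam = reduction / float(w @ _P_REDUCTION_SHAPE)
    factors = np.clip(1.0 - lam * _P_REDUCTION_SHAPE, 0.0, None)
    return DeltaChange(tuple(dtm), tuple(factors))


# ---------------------------------------------------------------------------
# Truth runs


def generate_truth_run(
    forcing: ClimateForcing,
    catchment: CatchmentSpec,
    true_params: ParameterSet,
    noise_sd: float = 0.1,
    missing_fraction: float = 0.11,
    seed: int = 0,
    spinup_days: int = 365,
    n_gaps: int = 6,
    snow: bool = True,
) -> tuple[DailySeries, SimulationResult]:
    """Synthetic observed record from a known-parameter model run.

    Observations are the truth streamflow times multiplicative lognormal
    noise (median 1), with ``missing_fraction`` of the days masked in
    ``n_gaps`` contiguous blocks — the outage structure of a real pressure
    sensor record.  Returns ``(obs, truth)``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= missing_fraction <= 0.5:
        raise ValueError("missing_fraction must lie in [0, 0.5]")
    truth = simulate(forcing, catchment, true_params, spinup_days=spinup_days, snow=snow)
    q = truth.streamflow.values
    n = len(q)
    rng = np.random.default_rng(seed)
    obs = q * np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd > 0 else q.copy()

    total_missing = int(round(missing_fraction * n))
    if total_missing > 0:
        k = min(n_gaps, total_missing)
        lengths = rng.multinomial(total_missing, [1.0 / k] * k)
        # one gap per equal segment of the record, placed at a random offset
        bounds = np.linspace(0, n, k + 1).astype(int)
        for j, length in enumerate(lengths):
            length = int(min(length, bounds[j + 1] - bounds[j]))
            if length == 0:
                continue
            start = int(rng.integers(bounds[j], bounds[j + 1] - length + 1))
            obs[start:start + length] = np.nan
    return DailySeries(truth.streamflow.start, obs, MM_PER_DAY), truth
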