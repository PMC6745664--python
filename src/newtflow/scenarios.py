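"""Vegetation-cover scenario arithmetic and the climate x vegetation matrix.

Four vegetation storylines for the Montseny reference catchment (holm oak
expanding uphill at the expense of beech and heathland):

* **i**   — covers as present;
* **ii**  — holm oak takes over 50% of the beech area, beech takes over
  50% of the heathland area ("beech increased");
* **iii** — holm oak takes over 50% of the beech area, heathland untouched
  ("heathland protected");
* **iv**  — holm oak covers the whole catchment.

Crossed with 2 future periods x 2 climate pathways they form the 16-run
scenario matrix; each run reuses the single calibrated parameter set and
the *fixed* reference-derived ecological thresholds — thresholds are never
recomputed from a simulated series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .buckets import ParameterSet, simulate
from .events import EventSummary, ThresholdSpec, summarize_events
from .series import CatchmentSpec, ClimateForcing

PERIODS = ("near", "far")            # 2031-2050 and 2081-2100
CLIMATES = ("rcp45", "rcp85")
VEGETATION_SCENARIOS = ("i", "ii", "iii", "iv")


@dataclass(frozen=True)
class Scenario:
    period: str
    climate: str
    vegetation: str

    def __post_init__(self) -> None:
        if self.period not in PERIODS + ("reference",):
            raise ValueError(f"unknown period {self.period!r}")
        if self.climate not in CLIMATES + ("historical",):
            raise ValueError(f"unknown climate {self.climate!r}")
        if self.vegetation not in VEGETATION_SCENARIOS:
            raise ValueError(f"unknown vegetation scenario {self.vegetation!r}")
        if (self.period == "reference") != (self.climate == "historical"):
            raise ValueError("the reference period pairs only with historical climate")


REFERENCE = Scenario("reference", "historical", "i")


def apply_vegetation_scenario(cover: CatchmentSpec, scenario_id: str) -> CatchmentSpec:
    """Transform cover fractions according to a vegetation storyline."""
    h = cover.cover_fractions["holm_oak"]
    b = cover.cover_fractions["beech"]
    e = cover.cover_fractions["heathland"]
    if scenario_id == "i":
        new = {"holm_oak": h, "beech": b, "heathland": e}
    elif scenario_id == "ii":
        new = {"holm_oak": h + b / 2, "beech": b / 2 + e / 2, "heathland": e / 2}
    elif scenario_id == "iii":
        new = {"holm_oak": h + b / 2, "beech": b / 2, "heathland": e}
    elif scenario_id == "iv":
        new = {"holm_oak": 1.0, "beech": 0.0, "heathland": 0.0}
    else:
        raise ValueError(f"unknown vegetation scenario {scenario_id!r}")
    return cover.with_covers(new)


def percent_change(value: float, reference: float) -> float:
    """Percent *decrease* from the reference: ``100*(ref - value)/ref``."""
    if reference == 0:
        raise ValueError("percent change undefined for a zero reference")
    return 100.0 * (reference - value) / reference


@dataclass
class ScenarioResult:
    """Event summaries for the reference run and the 16-cell matrix."""

    reference: EventSummary
    scenarios: dict[Scenario, EventSummary]

    def __post_init__(self) -> None:
        expected = {
            Scenario(p, c, v) for p in PERIODS for c in CLIMATES for v in VEGETATION_SCENARIOS
        }
        missing = expected - set(self.scenarios)
        if missing:
            raise ValueError(f"incomplete scenario matrix; missing {sorted(map(str, missing))}")

    def anova_input(self, response: str = "days_below") -> dict[tuple[str, str, str], float]:
        """The 16 outcomes keyed (period, climate, vegetation) for the ANOVA."""
        getter = {
            "days_below": lambda s: s.days_below,
            "events_above_all": lambda s: s.events_above_all,
            "events_above_dry": lambda s: s.events_above_dry,
            "annual_q": lambda s: s.annual_q,
        }[response]
        return {
            (sc.period, sc.climate, sc.vegetation): float(getter(summary))
            for sc, summary in self.scenarios.items()
        }

    def table(self) -> pd.DataFrame:
        """Scenario-summary table: one row per run, reference first."""
        rows = [_row(REFERENCE, self.reference, self.reference)]
        for p in PERIODS:
            for c in CLIMATES:
                for v in VEGETATION_SCENARIOS:
                    sc = Scenario(p, c, v)
                    rows.append(_row(sc, self.scenarios[sc], self.reference))
        return pd.DataFrame(rows)


def _row(sc: Scenario, s: EventSummary, ref: EventSummary) -> dict:
    return {
        "period": sc.period,
        "climate": sc.climate,
        "vegetation": sc.vegetation,
        "qlow_days": s.days_below,
        "qlow_events": s.events_below,
        "qdiffall_days": s.events_above_all,
        "qdiffdry_days": s.events_above_dry,
        "q_mm_year": s.annual_q,
        "q_decrease_percent": percent_change(s.annual_q, ref.annual_q),
        "fraction_below": s.fraction_below,
    }


def run_matrix(
    best_set: ParameterSet,
    forcings: Mapping[tuple[str, str], ClimateForcing],
    base_cover: CatchmentSpec,
    thresholds: ThresholdSpec,
    spinup_days: int = 365,
    snow: bool = True,
) -> ScenarioResult:
    """Simulate the reference run and all 16 (period, climate, vegetation) cells.

    ``forcings`` maps ``("reference", "historical")`` and every
    ``(period, climate)`` pair to its forcing; the calibrated parameter set
    and the reference-derived thresholds are held fixed across all runs.
    """
    required = [("reference", "historical")] + [(p, c) for p in PERIODS for c in CLIMATES]
    missing = [k for k in required if k not in forcings]
    if missing:
        raise ValueError(f"missing forcing series for {missing}")

    def run(key: tuple[str, str], veg: str) -> EventSummary:
        cover = apply_vegetation_scenario(base_cover, veg)
        sim = simulate(forcings[key], cover, best_set, spinup_days=spinup_days, snow=snow)
        return summarize_events(sim.streamflow, thresholds)

    reference = run(("reference", "historical"), "i")
    scenarios = {
        Scenario(p, c, v): run((p, c), v)
        for p in PERIODS for c in CLIMATES for v in VEGETATION_SCENARIOS
    }
    return ScenarioResult(reference=reference, scenarios=scenarios)
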