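"""Bundled reference tables for the Montseny study catchment.

The published climate-x-vegetation scenario summary for the 2 km**2
Montseny reference catchment ships as package data: per scenario, days
below Q_low (0.33 L/s), consecutive-day low-flow events, single-day spate
events above the Q_diff thresholds (97 and 42 L/s), and annual streamflow.
These printed values are inputs for the variance-partitioning and
worked-example paths; they are never used to calibrate or fit anything.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

RESPONSE_COLUMNS = ("qlow_days", "qlow_events", "qdiffall_days", "qdiffdry_days", "q_mm_year")


def load_published_scenario_table() -> pd.DataFrame:
    """Scenario summary table (reference row first, then the 16-cell matrix)."""
    with resources.files("newtflow.data").joinpath("montseny_scenario_table.csv").open() as fh:
        return pd.read_csv(fh)


def published_anova_input(response: str = "qlow_days") -> dict[tuple[str, str, str], float]:
    """The 16 future-scenario outcomes keyed (period, climate, vegetation)."""
    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"unknown response {response!r}; choose from {RESPONSE_COLUMNS}")
    table = load_published_scenario_table()
    future = table[table["period"] != "reference"]
    return {
        (row.period, row.climate, row.vegetation): float(getattr(row, response))
        for row in future.itertuples()
    }
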