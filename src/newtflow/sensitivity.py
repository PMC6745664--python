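"""Parameter-sensitivity classification from elite calibration samples.

If streamflow simulations are insensitive to a parameter, the values of
that parameter among the best-performing Monte-Carlo samples stay spread
out like the rectangular (uniform) sampling distribution.  Sensitivity
therefore shows up as a significant one-sample Kolmogorov-Smirnov departure
from uniformity on the *initial* sampling range — the refined ranges are
non-uniform by construction, which is exactly the signal being read.
Family-wise error across the tested parameters is controlled by Bonferroni
(adjusted p < alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .buckets import ParameterSet
from .calibrate import CalibrationResult

DEFAULT_ALPHA = 0.01
MIN_SETS = 30


def ks_uniform_test(values: Sequence[float], low: float, high: float) -> tuple[float, float]:
    """One-sample KS test of ``values`` against Uniform(low, high).

    Exact p-values where scipy provides them (n <= ~100), asymptotic
    otherwise; ties sit on the right-continuous empirical CDF.
    """
    v = np.asarray(values, dtype=float)
    if low >= high:
        raise ValueError("low must be < high")
    if len(v) < 5:
        raise ValueError("need at least 5 values")
    if np.any(v < low) or np.any(v > high):
        raise ValueError(
            "values outside [low, high]; the range does not match the calibration"
        )
    method = "exact" if len(v) <= 100 else "asymp"
    res = stats.kstest(v, stats.uniform(loc=low, scale=high - low).cdf, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SensitivityReport:
    """Per-parameter KS statistics, ordered by D descending."""

    table: pd.DataFrame          # columns: parameter, D, p, sensitive
    alpha: float
    adjusted_alpha: float

    @property
    def sensitive_parameters(self) -> list[str]:
        return list(self.table.loc[self.table["sensitive"], "parameter"])


def classify_sensitivity(
    top_sets: CalibrationResult | Sequence[ParameterSet] | np.ndarray,
    ranges: Mapping[str, tuple[float, float]],
    alpha: float = DEFAULT_ALPHA,
    min_sets: int = MIN_SETS,
) -> SensitivityReport:
    """Flag parameters whose elite-sample distribution is non-rectangular.

    ``top_sets`` may be a :class:`CalibrationResult`, a sequence of
    :class:`ParameterSet`, or an ``(n_sets, n_parameters)`` array in the
    order of ``ranges``.  ``ranges`` must be the *initial* sampling ranges.
    A parameter is sensitive iff its raw p-value is below
    ``alpha / n_parameters`` (Bonferroni).
    """
    names = tuple(ranges)
    if isinstance(top_sets, CalibrationResult):
        values = np.stack([ps.to_vector(names) for ps, _, _ in top_sets.top_sets])
    elif isinstance(top_sets, np.ndarray):
        values = np.asarray(top_sets, dtype=float)
        if values.shape[1] != len(names):
            raise ValueError("array width must match the number of ranged parameters")
    else:
        values = np.stack([ps.to_vector(names) for ps in top_sets])
    if len(values) < min_sets:
        raise ValueError(f"need at least {min_sets} parameter sets, got {len(values)}")

    adjusted = alpha / len(names)
    rows = []
    for j, name in enumerate(names):
        low, high = ranges[name]
        d, p = ks_uniform_test(values[:, j], low, high)
        rows.append({"parameter": name, "D": d, "p": p, "sensitive": p < adjusted})
    table = (
        pd.DataFrame(rows)
        .sort_values("D", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return SensitivityReport(table=table, alpha=alpha, adjusted_alpha=adjusted)
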