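"""Main-effects variance partitioning of the scenario matrix.

A three-way main-effects ANOVA (period: 2 levels, climate: 2, vegetation:
4; no interactions) decomposes the variation of an outcome across the 16
scenario cells.  Each factor's share is its sum of squares over the total
sum of squares; what the main effects leave unexplained is the residual.
A saturated model on a single-replicate 2x2x4 design would have zero
residual by construction, so interactions are deliberately excluded — the
residual is the interaction variance, reported as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .series import round_half_up

FACTORS = ("period", "climate", "vegetation")
_EXPECTED_LEVELS = {"period": 2, "climate": 2, "vegetation": 4}


@dataclass
class VariancePartition:
    """Percent of total sum of squares per component.

    ``model`` is the sum of the three factor shares; ``model + residual``
    is 100 up to rounding noise; every share is >= 0 in a balanced design.
    """

    fractions: dict[str, float]

    def rounded(self) -> dict[str, float]:
        """Reporting convention: integer percent, one decimal below 1%."""
        return {
            k: round_half_up(v, 1) if v < 1.0 else round_half_up(v)
            for k, v in self.fractions.items()
        }


def main_effects_anova(
    values: Mapping[tuple[str, str, str], float]
) -> VariancePartition:
    """Partition the 16 outcomes keyed ``(period, climate, vegetation)``.

    Requires the complete balanced 2x2x4 crossing with one value per cell.
    ``SS_factor = sum over levels of n_level*(level mean - grand mean)^2``;
    fractions are percents of the total sum of squares about the grand
    mean.  An all-equal outcome yields an all-zero partition with a
    warning.
    """
    keys = list(values)
    levels = [sorted({k[i] for k in keys}) for i in range(3)]
    for f, lev in zip(FACTORS, levels):
        if len(lev) != _EXPECTED_LEVELS[f]:
            raise ValueError(
                f"factor {f!r} has levels {lev}; expected {_EXPECTED_LEVELS[f]}"
            )
    expected = {(p, c, v) for p in levels[0] for c in levels[1] for v in levels[2]}
    missing = expected - set(keys)
    if missing:
        raise ValueError(f"incomplete design; missing cells {sorted(missing)}")
    if len(keys) != len(expected):
        raise ValueError("duplicate cells in design")

    y = np.array([float(values[k]) for k in keys])
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0.0:
        warnings.warn("all outcomes equal; variance partition is identically zero",
                      stacklevel=2)
        fractions = {f: 0.0 for f in FACTORS}
        fractions["model"] = 0.0
        fractions["residual"] = 0.0
        return VariancePartition(fractions)

    fractions: dict[str, float] = {}
    for i, f in enumerate(FACTORS):
        ss = 0.0
        for lev in levels[i]:
            mask = np.array([k[i] == lev for k in keys])
            ss += mask.sum() * (y[mask].mean() - grand) ** 2
        fractions[f] = 100.0 * ss / ss_total
    fractions["model"] = fractions["period"] + fractions["climate"] + fractions["vegetation"]
    fractions["residual"] = 100.0 - fractions["model"]
    return VariancePartition(fractions)
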