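"""Bundled reference measurements for skin-derived CWM in model wine.

``DESORPTION_REFERENCE`` holds the measured mean percent desorption of PA
(relative to the amount bound at the initial 15 degC equilibrium) with sample
standard deviations (n = 3), after sequential re-equilibration at 22.5, 30
and 35 degC in model wines of 0, 7.5, 12 and 15 % v/v ethanol.  These values
drive the default fractions of the empirical ramp mode and the default
final desorption fraction of the winemaking scenario.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DESORPTION_REFERENCE",
    "desorption_reference",
    "empirical_fractions",
    "FINAL_DESORPTION_FRACTION",
]

_ROWS = [
    # ethanol_pct, temperature_C, mean_pct, sd_pct
    (0.0, 22.5, 2.82, 3.39),
    (0.0, 30.0, 7.49, 5.51),
    (0.0, 35.0, 13.35, 5.62),
    (7.5, 22.5, 8.60, 2.01),
    (7.5, 30.0, 22.30, 3.58),
    (7.5, 35.0, 27.88, 3.38),
    (12.0, 22.5, 17.48, 1.46),
    (12.0, 30.0, 25.24, 9.94),
    (12.0, 35.0, 31.59, 10.26),
    (15.0, 22.5, 26.73, 0.37),
    (15.0, 30.0, 37.36, 1.71),
    (15.0, 35.0, 47.96, 3.37),
]

DESORPTION_REFERENCE = pd.DataFrame(
    _ROWS, columns=["ethanol_pct", "temperature_C", "mean_pct", "sd_pct"]
)
DESORPTION_REFERENCE["n"] = 3

#: Measured desorption fraction at the finished-wine condition (35 degC, 15 %).
FINAL_DESORPTION_FRACTION = 0.4796


def desorption_reference() -> pd.DataFrame:
    """A defensive copy of the reference desorption table."""
    return DESORPTION_REFERENCE.copy()


def empirical_fractions(ethanol_pct: float) -> list[float]:
    """Per-step desorption fractions (of the 15 degC bound mass) at one ethanol level.

    Ordered by temperature (22.5, 30, 35 degC); fractions are the reference
    means divided by 100.
    """
    sub = DESORPTION_REFERENCE[DESORPTION_REFERENCE["ethanol_pct"] == ethanol_pct]
    if sub.empty:
        raise KeyError(
            f"no reference desorption data at ethanol {ethanol_pct!r} % "
            f"(available: {sorted(DESORPTION_REFERENCE['ethanol_pct'].unique())})"
        )
    return list(sub.sort_values("temperature_C")["mean_pct"] / 100.0)
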