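"""Summary statistics for the desorption experiment.

Covers the triplicate mean +/- SD desorption table, significance letters
from one-way ANOVA with Tukey HSD post-hoc comparisons, and the
model-versus-data error report for Langmuir predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sorption import (
    Condition,
    RationalSurfaceCoefficients,
    DEFAULT_KEQ_COEFFS,
    DEFAULT_SCWM_COEFFS,
    isotherm_q,
    langmuir_parameters,
)

__all__ = [
    "ModelComparisonReport",
    "summarize_desorption",
    "anova_letters",
    "model_error",
]


def summarize_desorption(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sample SD percent desorption per (ethanol, temperature) cell.

    Parameters
    ----------
    per_replicate : DataFrame
        Columns ``ethanol_pct, temperature_C, replicate, percent_desorption``
        (one row per replicate).

    Returns
    -------
    DataFrame with columns ``ethanol_pct, temperature_C, mean_pct, sd_pct, n``.
    The SD uses the n-1 denominator; a single-replicate cell reports NaN.
    """
    required = {"ethanol_pct", "temperature_C", "percent_desorption"}
    missing = required - set(per_replicate.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if per_replicate.empty:
        raise ValueError("no replicate rows supplied")
    grouped = (
        per_replicate.groupby(["ethanol_pct", "temperature_C"])["percent_desorption"]
        .agg(mean_pct="mean", sd_pct=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    empty = grouped[grouped["n"] == 0]
    if not empty.empty:
        cell = empty.iloc[0]
        raise ValueError(
            f"empty cell at ethanol {cell.ethanol_pct} %, {cell.temperature_C} degC"
        )
    return grouped


def _compact_letter_display(names, means, distinct_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    ``distinct_pairs`` holds index pairs that are significantly different.
    Start from one letter column holding every group; for each significant
    pair split any column containing both members, then absorb columns that
    became subsets of another.  Letters are assigned in ascending order of
    the column's smallest mean, so 'a' marks the smallest means.
    """
    columns: list[set] = [set(range(len(names)))]
    for i, j in distinct_pairs:
        next_columns: list[set] = []
        for col in columns:
            if i in col and j in col:
                next_columns.append(col - {i})
                next_columns.append(col - {j})
            else:
                next_columns.append(col)
        # absorb: drop duplicates and columns contained in another
        columns = [
            col
            for k, col in enumerate(next_columns)
            if col
            and not any(
                (col < other) or (col == other and k > m)
                for m, other in enumerate(next_columns)
            )
        ]
    columns.sort(key=lambda col: min(means[idx] for idx in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for j, col in enumerate(columns):
        for idx in col:
            out[names[idx]] += alphabet[j % len(alphabet)]
    return {k: "".join(sorted(v)) for k, v in out.items()}


def anova_letters(groups: dict, alpha: float = 0.05) -> dict:
    """Compact letter display from one-way ANOVA + Tukey HSD.

    Parameters
    ----------
    groups : dict mapping group name -> sequence of replicate values
        At least two groups with at least two replicates each.
    alpha : float
        Significance level for both the omnibus ANOVA and the pairwise test.

    Returns
    -------
    dict mapping group name -> letter string; groups sharing any letter are
    not significantly different.  'a' is assigned to the smallest mean.

    Notes
    -----
    When every group has zero internal variance the F statistic is undefined;
    groups are then clustered by exact value equality instead.
    """
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(d) < 2 for d in data):
        raise ValueError("each group needs >= 2 replicates")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    means = np.array([d.mean() for d in data])

    if all(np.ptp(d) == 0 for d in data):
        # degenerate: no within-group variance; cluster by exact equality
        distinct = [
            (i, j)
            for i in range(len(data))
            for j in range(i + 1, len(data))
            if data[i][0] != data[j][0]
        ]
        return _compact_letter_display(names, means, distinct)

    _, p_omnibus = sps.f_oneway(*data)
    if not p_omnibus < alpha:
        return {n: "a" for n in names}
    tukey = sps.tukey_hsd(*data)
    distinct = [
        (i, j)
        for i in range(len(data))
        for j in range(i + 1, len(data))
        if tukey.pvalue[i, j] < alpha
    ]
    return _compact_letter_display(names, means, distinct)


@dataclass(frozen=True)
class ModelComparisonReport:
    """Model-versus-data errors for one (ethanol, temperature) cell.

    mae : mean absolute error in q (mg/mg).
    mpe : mean absolute percent error, observed q as denominator (%).
    bias : signed mean of (predicted - observed) q; positive means the
        model overestimates adsorption.
    n_points : points contributing to the MAE.
    n_excluded_mpe : points with observed q = 0, excluded from the MPE.
    """

    mae: float
    mpe: float
    bias: float
    n_points: int
    n_excluded_mpe: int

    @property
    def direction(self) -> str:
        if self.bias > 0:
            return "overestimates"
        if self.bias < 0:
            return "underestimates"
        return "unbiased"


def model_error(
    points: pd.DataFrame,
    keq_coeffs: RationalSurfaceCoefficients = DEFAULT_KEQ_COEFFS,
    scwm_coeffs: RationalSurfaceCoefficients = DEFAULT_SCWM_COEFFS,
) -> pd.DataFrame:
    """Per-condition error between observed isotherm points and the model.

    Parameters
    ----------
    points : DataFrame
        Columns ``ethanol_pct, temperature_C, c_mg_per_L, q_mg_per_mg``
        (observed q at dissolved concentration c).

    Returns
    -------
    DataFrame with one row per (ethanol_pct, temperature_C) carrying the
    fields of :class:`ModelComparisonReport` plus a ``direction`` label.
    """
    required = {"ethanol_pct", "temperature_C", "c_mg_per_L", "q_mg_per_mg"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if points.empty:
        raise ValueError("no points supplied")

    rows = []
    for (eth, temp), sub in points.groupby(["ethanol_pct", "temperature_C"]):
        params = langmuir_parameters(
            Condition.from_celsius(temp, eth), keq_coeffs, scwm_coeffs
        )
        q_obs = sub["q_mg_per_mg"].to_numpy(dtype=float)
        q_pred = isotherm_q(sub["c_mg_per_L"].to_numpy(dtype=float), params)
        resid = q_pred - q_obs
        nonzero = q_obs != 0
        mpe = (
            float(np.mean(np.abs(resid[nonzero]) / q_obs[nonzero]) * 100.0)
            if nonzero.any()
            else np.nan
        )
        report = ModelComparisonReport(
            mae=float(np.mean(np.abs(resid))),
            mpe=mpe,
            bias=float(np.mean(resid)),
            n_points=len(q_obs),
            n_excluded_mpe=int((~nonzero).sum()),
        )
        rows.append(
            {
                "ethanol_pct": eth,
                "temperature_C": temp,
                "mae_mg_per_mg": report.mae,
                "mpe_pct": report.mpe,
                "bias_mg_per_mg": report.bias,
                "direction": report.direction,
                "n_points": report.n_points,
                "n_excluded_mpe": report.n_excluded_mpe,
            }
        )
    return pd.DataFrame(rows)
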