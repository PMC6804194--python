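"""Synthetic assay data with the statistical structure of the bench experiment.

Generators produce triplicate control/trial absorbance series over the
temperature ramp, isotherm point sets, phloroglucinolysis subunit profiles
and GPC traces from known ground truth, with seeded multiplicative Gaussian
noise.  Noise is applied to concentrations by default (measurement scatter
in the desorption data grows with the mean, pointing at a multiplicative
error structure); placing it on absorbances instead is configurable.

Every generator is a pure function of (truth, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssayCalibration, absorbance_from_concentration
from .composition import GPCTrace, SubunitProfile
from .ramp import RampResult
from .sorption import LangmuirParameters, isotherm_q

__all__ = [
    "NoiseModel",
    "generate_measurements",
    "generate_isotherm_points",
    "generate_subunit_profile",
    "generate_gpc_trace",
    "default_gpc_calibration",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise specification.

    cv : coefficient of variation of the multiplicative factor.
    seed : RNG seed (generators are deterministic per seed).
    replicates : replicate count per condition (bench default 3).
    placement : "concentration" (default) or "absorbance" - which quantity
        the noise factor multiplies.
    """

    cv: float
    seed: int
    replicates: int = 3
    placement: str = "concentration"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.placement not in ("concentration", "absorbance"):
            raise ValueError(f"unknown noise placement {self.placement!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy(value: float, cv: float, rng: np.random.Generator) -> float:
    return float(value) * (1.0 + cv * rng.standard_normal()) if cv else float(value)


def generate_measurements(
    truth: RampResult,
    cal: AssayCalibration,
    noise: NoiseModel,
    *,
    condition_id: str | None = None,
    a_background: float = 0.05,
) -> pd.DataFrame:
    """Triplicate control/trial absorbance readings over the ramp.

    Control rows carry the dissolved concentration of a CWM-free system
    (constant at total PA / volume); trial rows carry the per-step
    equilibrium concentrations of ``truth``.  Absorbances are generated by
    inverting the calibration, after (default) or before noise is applied
    according to ``noise.placement``.

    Returns a tidy DataFrame with columns ``condition_id, ethanol_pct,
    temperature_C, replicate, role, a_background, a_final``.
    """
    rng = noise.rng()
    eth = truth.schedule.ethanol_pct
    cid = condition_id if condition_id is not None else f"etoh{eth:g}"
    control_conc = truth.system.total_pa_mg / truth.system.liquid_volume_L

    rows = []
    for temp, state in zip(truth.schedule.temperatures_C, truth.states):
        for role, conc in (("control", control_conc), ("trial", state.c_pa_mg_per_L)):
            for rep in range(1, noise.replicates + 1):
                if noise.placement == "concentration":
                    reading = absorbance_from_concentration(
                        max(_noisy(conc, noise.cv, rng), 0.0), cal, a_background
                    )
                else:
                    clean = absorbance_from_concentration(conc, cal, a_background)
                    reading = type(clean)(
                        a_background=clean.a_background,
                        a_final=max(_noisy(clean.a_final, noise.cv, rng), 0.0),
                    )
                rows.append(
                    {
                        "condition_id": cid,
                        "ethanol_pct": eth,
                        "temperature_C": temp,
                        "replicate": rep,
                        "role": role,
                        "a_background": reading.a_background,
                        "a_final": reading.a_final,
                    }
                )
    return pd.DataFrame(rows)


def generate_isotherm_points(
    params: LangmuirParameters, c_grid, noise: NoiseModel
) -> pd.DataFrame:
    """Noisy (c, q) isotherm points on a concentration grid.

    q = isotherm_q(c) x a multiplicative noise factor, ``noise.replicates``
    points per grid concentration.  Columns ``c_mg_per_L, q_mg_per_mg``.
    """
    grid = np.asarray(c_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("c_grid must be non-empty")
    rng = noise.rng()
    rows = []
    for c in grid:
        q_true = isotherm_q(float(c), params)
        for _ in range(noise.replicates):
            rows.append(
                {"c_mg_per_L": float(c), "q_mg_per_mg": max(_noisy(q_true, noise.cv, rng), 0.0)}
            )
    return pd.DataFrame(rows)


def generate_subunit_profile(
    target_mdp: float,
    pct_gallo: float,
    pct_galloylation: float,
    total_nmol: float = 100.0,
    seed: int = 0,
    jitter_cv: float = 0.0,
) -> SubunitProfile:
    """A subunit profile realizing target mDP / % gallo / % galloylation.

    Species mole fractions are set directly from the percentage targets
    (epigallocatechin and epicatechin gallate), the remainder split 1:3
    between catechin and epicatechin as is typical of grape PA.  Each
    species is divided between terminal and extension positions in the
    ratio 1/mdp : (1 - 1/mdp), which realizes the targets exactly.  An
    optional seeded jitter (``jitter_cv`` > 0) perturbs the overall scale
    and each species' terminal/extension split; species totals keep their
    exact proportions, so the percentage targets are unaffected and only
    mDP moves slightly.
    """
    if target_mdp < 1:
        raise ValueError(f"target_mdp must be >= 1, got {target_mdp}")
    if pct_gallo < 0 or pct_galloylation < 0 or pct_gallo + pct_galloylation > 100:
        raise ValueError(
            f"infeasible targets: pct_gallo={pct_gallo}, "
            f"pct_galloylation={pct_galloylation} (must be >= 0, sum <= 100)"
        )
    if total_nmol <= 0:
        raise ValueError("total_nmol must be > 0")

    rest = 1.0 - (pct_gallo + pct_galloylation) / 100.0
    fractions = {
        "epigallocatechin": pct_gallo / 100.0,
        "epicatechin_gallate": pct_galloylation / 100.0,
        "catechin": 0.25 * rest,
        "epicatechin": 0.75 * rest,
    }
    rng = np.random.default_rng(seed)
    scale = max(_noisy(1.0, jitter_cv, rng), 0.1)
    amounts = {}
    for species, frac in fractions.items():
        if frac == 0:
            continue
        terminal_share = min(max(_noisy(1.0 / target_mdp, jitter_cv, rng), 0.0), 1.0)
        species_nmol = total_nmol * frac * scale
        for position, share in (("terminal", terminal_share), ("extension", 1.0 - terminal_share)):
            if species_nmol * share > 0:
                amounts[(species, position)] = species_nmol * share
    return SubunitProfile(amounts=amounts)


def default_gpc_calibration(
    elution_range_mL: tuple[float, float] = (10.0, 30.0),
    log10_mw_range: tuple[float, float] = (5.0, 2.0),
    n_points: int = 11,
) -> tuple[np.ndarray, np.ndarray]:
    """A linear elution -> log10 MW calibration (large molecules elute first)."""
    elution = np.linspace(*elution_range_mL, n_points)
    log10_mw = np.linspace(*log10_mw_range, n_points)
    return elution, log10_mw


def generate_gpc_trace(
    components,
    calibration: tuple | None = None,
    seed: int = 0,
    n_points: int = 400,
    noise_cv: float = 0.0,
) -> GPCTrace:
    """A GPC trace from a mixture of lognormal mass components.

    Parameters
    ----------
    components : sequence of (mean_log10_mw, sd_log10_mw, mass_fraction)
        Mass fractions must sum to 1.
    calibration : (elution_mL, log10_mw) arrays, optional
        Defaults to :func:`default_gpc_calibration`.
    noise_cv : float
        Optional multiplicative noise on the signal (seeded).
    """
    comps = [(float(m), float(s), float(f)) for m, s, f in components]
    if not comps:
        raise ValueError("need >= 1 mixture component")
    if any(s <= 0 for _, s, _ in comps):
        raise ValueError("component sd must be > 0")
    total_frac = sum(f for _, _, f in comps)
    if abs(total_frac - 1.0) > 1e-8:
        raise ValueError(f"mass fractions must sum to 1, got {total_frac}")

    cal_elution, cal_log10_mw = (
        calibration if calibration is not None else default_gpc_calibration()
    )
    cal_elution = np.asarray(cal_elution, dtype=float)
    cal_log10_mw = np.asarray(cal_log10_mw, dtype=float)

    elution = np.linspace(cal_elution[0], cal_elution[-1], n_points)
    x = np.interp(elution, cal_elution, cal_log10_mw)  # log10 MW per sample
    # mass density over log10 MW, mapped to the elution axis via |dx/dV|
    density = np.zeros_like(x)
    for mean, sd, frac in comps:
        density += frac * np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    signal = density * np.abs(np.gradient(x, elution))
    if noise_cv:
        rng = np.random.default_rng(seed)
        signal = np.clip(signal * (1.0 + noise_cv * rng.standard_normal(signal.size)), 0.0, None)
    return GPCTrace(
        elution_mL=elution,
        signal=signal,
        cal_elution_mL=cal_elution,
        cal_log10_mw=cal_log10_mw,
    )
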