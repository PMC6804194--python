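"""Langmuir adsorption of proanthocyanidins (PA) on grape cell-wall material.

The single-layer Langmuir isotherm

    q(C) = K * C * S / (1 + K * C)

relates the dissolved PA concentration ``C`` (mg catechin units per L) to the
adsorbed amount ``q`` (mg PA per mg CWM), through the equilibrium constant
``K`` (L/mg) and the saturation capacity ``S`` (mg/mg).  Both parameters vary
with temperature and ethanol content of the model wine; they are generated by
rational surfaces of the form

    (n0 + nT*T + nE*E) / (d0 + dT*T + dE*E + dTE*T*E)

with ``T`` in Kelvin and ``E`` in % v/v ethanol, calibrated over 15-35 degC
and 0-15 % ethanol.  This module evaluates those surfaces, solves the closed
liquid-solid batch equilibrium by mass balance, and fits (K, S) to isotherm
points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateSystemError,
    ExtrapolationWarning,
    FitFailureError,
    InvalidParameterError,
    SingularSurfaceError,
)

__all__ = [
    "Condition",
    "RationalSurfaceCoefficients",
    "LangmuirParameters",
    "BatchSystem",
    "EquilibriumState",
    "LangmuirFit",
    "DEFAULT_KEQ_COEFFS",
    "DEFAULT_SCWM_COEFFS",
    "CALIBRATED_T_CELSIUS",
    "CALIBRATED_ETHANOL_PCT",
    "evaluate_surface",
    "langmuir_parameters",
    "isotherm_q",
    "solve_batch_equilibrium",
    "fit_langmuir",
]

#: Calibrated envelope of the parameter surfaces.
CALIBRATED_T_CELSIUS = (15.0, 35.0)
CALIBRATED_ETHANOL_PCT = (0.0, 15.0)

_KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class Condition:
    """A (temperature, ethanol) operating point of the model-wine system.

    Parameters
    ----------
    temperature_K : float
        Absolute temperature in Kelvin.  Use :meth:`from_celsius` at the
        user-facing boundary; files and CLI speak Celsius.
    ethanol_pct : float
        Ethanol concentration in % v/v.
    """

    temperature_K: float
    ethanol_pct: float

    def __post_init__(self) -> None:
        if not self.temperature_K > 0:
            raise ValueError(f"temperature_K must be > 0, got {self.temperature_K}")
        if self.ethanol_pct < 0:
            raise ValueError(f"ethanol_pct must be >= 0, got {self.ethanol_pct}")

    @classmethod
    def from_celsius(cls, temperature_C: float, ethanol_pct: float) -> "Condition":
        return cls(temperature_C + _KELVIN_OFFSET, ethanol_pct)

    @property
    def temperature_C(self) -> float:
        return self.temperature_K - _KELVIN_OFFSET

    @property
    def is_extrapolated(self) -> bool:
        """True outside the calibrated 15-35 degC / 0-15 % envelope."""
        lo_t, hi_t = CALIBRATED_T_CELSIUS
        lo_e, hi_e = CALIBRATED_ETHANOL_PCT
        return not (lo_t <= self.temperature_C <= hi_t and lo_e <= self.ethanol_pct <= hi_e)


@dataclass(frozen=True)
class RationalSurfaceCoefficients:
    """Coefficients of one rational parameter surface.

    ``numerator`` holds (const, coef_T, coef_E); ``denominator`` holds
    (const, coef_T, coef_E, coef_TE).  ``label`` names the surface this set
    generates ("Keq" or "Scwm").
    """

    numerator: tuple[float, float, float]
    denominator: tuple[float, float, float, float]
    label: str = ""

    def __call__(self, cond: Condition) -> float:
        return evaluate_surface(self, cond)


#: Default surface constants for the equilibrium constant K_eq (L/mg C.U.).
DEFAULT_KEQ_COEFFS = RationalSurfaceCoefficients(
    numerator=(1.21e-3, -2.69e-1, 0.0),
    denominator=(0.0, -9.01, -1.25e2, 1.0),
    label="Keq",
)

#: Default surface constants for the saturation capacity S_CWM (mg/mg CWM).
DEFAULT_SCWM_COEFFS = RationalSurfaceCoefficients(
    numerator=(4.57e1, 0.0, 2.04e1),
    denominator=(0.0, 4.57e-1, -6.69, 1.0),
    label="Scwm",
)


@dataclass(frozen=True)
class LangmuirParameters:
    """Langmuir isotherm constants at one condition.

    keq : equilibrium constant, L per mg PA (catechin units).
    scwm : saturation capacity, mg PA (C.U.) per mg CWM.
    """

    keq: float
    scwm: float

    def __post_init__(self) -> None:
        if not (self.keq > 0 and math.isfinite(self.keq)):
            raise InvalidParameterError(f"keq must be finite and > 0, got {self.keq}")
        if not (self.scwm > 0 and math.isfinite(self.scwm)):
            raise InvalidParameterError(f"scwm must be finite and > 0, got {self.scwm}")


@dataclass(frozen=True)
class BatchSystem:
    """A closed liquid-solid system: solution volume, adsorbent, total PA.

    The total PA mass (mg catechin units) is conserved between the dissolved
    and adsorbed pools: C*V + q*m = total.
    """

    liquid_volume_L: float
    cwm_mass_mg: float
    total_pa_mg: float

    def __post_init__(self) -> None:
        for name in ("liquid_volume_L", "cwm_mass_mg", "total_pa_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class EquilibriumState:
    """Solved equilibrium of a :class:`BatchSystem`."""

    c_pa_mg_per_L: float
    q_pa_mg_per_mg: float
    adsorbed_mg: float
    mass_residual: float


@dataclass(frozen=True)
class LangmuirFit:
    """Result of a least-squares Langmuir fit."""

    params: LangmuirParameters
    residual_norm: float
    converged: bool
    n_points: int
    covariance: np.ndarray = field(repr=False, default=None)


def evaluate_surface(coeffs: RationalSurfaceCoefficients, cond: Condition) -> float:
    """Evaluate a rational parameter surface at a condition.

    Returns (n0 + nT*T + nE*E) / (d0 + dT*T + dE*E + dTE*T*E) with T in
    Kelvin and E in % v/v.  Raises :class:`SingularSurfaceError` when the
    denominator is within tolerance of zero.
    """
    T, E = cond.temperature_K, cond.ethanol_pct
    n0, nT, nE = coeffs.numerator
    d0, dT, dE, dTE = coeffs.denominator
    num = n0 + nT * T + nE * E
    den = d0 + dT * T + dE * E + dTE * T * E
    # scale-aware singularity guard: compare against the magnitude of the terms
    scale = abs(d0) + abs(dT * T) + abs(dE * E) + abs(dTE * T * E)
    if abs(den) <= 1e-12 * max(scale, 1.0):
        raise SingularSurfaceError(
            f"surface {coeffs.label or '<unnamed>'} is singular at "
            f"T={cond.temperature_C:.2f} degC, E={E:g} % v/v"
        )
    return num / den


def langmuir_parameters(
    cond: Condition,
    keq_coeffs: RationalSurfaceCoefficients = DEFAULT_KEQ_COEFFS,
    scwm_coeffs: RationalSurfaceCoefficients = DEFAULT_SCWM_COEFFS,
) -> LangmuirParameters:
    """Langmuir (K, S) at a condition from the two parameter surfaces.

    Emits :class:`ExtrapolationWarning` outside the calibrated envelope and
    raises :class:`InvalidParameterError` when a surface value is
    non-positive (the model is not physically meaningful there).
    """
    if cond.is_extrapolated:
        warnings.warn(
            f"condition T={cond.temperature_C:.2f} degC, E={cond.ethanol_pct:g} % "
            "lies outside the calibrated envelope (15-35 degC, 0-15 %); "
            "surface values are extrapolations",
            ExtrapolationWarning,
            stacklevel=2,
        )
    keq = evaluate_surface(keq_coeffs, cond)
    scwm = evaluate_surface(scwm_coeffs, cond)
    if keq <= 0 or scwm <= 0:
        raise InvalidParameterError(
            f"non-positive surface value at T={cond.temperature_C:.2f} degC, "
            f"E={cond.ethanol_pct:g} %: keq={keq:.4g}, scwm={scwm:.4g}"
        )
    return LangmuirParameters(keq=keq, scwm=scwm)


def isotherm_q(c_pa: float, params: LangmuirParameters):
    """Adsorbed PA per mg CWM at dissolved concentration ``c_pa`` (mg/L).

    Accepts scalars or arrays; values lie in [0, scwm).
    """
    c = np.asarray(c_pa, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_pa must be >= 0")
    q = params.keq * c * params.scwm / (1.0 + params.keq * c)
    return float(q) if np.isscalar(c_pa) else q


def solve_batch_equilibrium(system: BatchSystem, params: LangmuirParameters) -> EquilibriumState:
    """Solve the closed-system equilibrium C*V + q(C)*m = total for C.

    Substituting the isotherm into the mass balance yields a quadratic in C,

        K*V*C^2 + (V + K*(S*m - total))*C - total = 0,

    whose unique non-negative root is the physical equilibrium (the product
    of the roots is -total/(K*V) <= 0, so exactly one root is admissible).
    The root is computed in the cancellation-free form.
    """
    V, m, total = system.liquid_volume_L, system.cwm_mass_mg, system.total_pa_mg
    K, S = params.keq, params.scwm

    if total == 0:
        return EquilibriumState(0.0, 0.0, 0.0, 0.0)
    if V == 0:
        raise DegenerateSystemError("zero liquid volume with nonzero total PA")
    if m == 0:
        c = total / V
        return EquilibriumState(c, 0.0, 0.0, abs(c * V - total))

    a = K * V
    b = V + K * (S * m - total)
    disc = b * b + 4.0 * a * total
    if disc < 0:  # impossible for valid inputs; guard against NaN propagation
        raise DegenerateSystemError("negative discriminant in batch-equilibrium solve")
    sqrt_disc = math.sqrt(disc)
    if b >= 0:
        c = 2.0 * total / (b + sqrt_disc)
    else:
        c = (-b + sqrt_disc) / (2.0 * a)
    c_max = total / V
    if not (0.0 <= c <= c_max * (1.0 + 1e-12)):
        raise DegenerateSystemError(
            f"selected root C={c:.6g} outside the admissible range [0, {c_max:.6g}]"
        )
    c = min(c, c_max)
    q = isotherm_q(c, params)
    adsorbed = q * m
    residual = abs(c * V + adsorbed - total)
    return EquilibriumState(c, q, adsorbed, residual)


def fit_langmuir(points, *, max_nfev: int = 10000) -> LangmuirFit:
    """Least-squares Langmuir fit of (K, S) to isotherm points.

    Parameters
    ----------
    points : sequence of (c_pa, q_pa)
        Isotherm observations, mg/L and mg/mg.  At least three points and at
        least two distinct concentrations are required.

    Returns
    -------
    LangmuirFit
        Estimated parameters with the residual 2-norm and convergence flag.

    Notes
    -----
    Starting values follow standard isotherm-fitting practice: the capacity
    starts at 1.1x the largest observed q and K at the reciprocal of the
    median concentration; both parameters are bounded below by zero.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitFailureError("need >= 3 (c, q) points")
    c, q = pts[:, 0], pts[:, 1]
    if np.any(c < 0) or np.any(q < 0):
        raise FitFailureError("isotherm points must be non-negative")
    if np.unique(c).size < 2:
        raise FitFailureError("degenerate design: need >= 2 distinct concentrations")
    if np.all(q == 0):
        raise FitFailureError("null isotherm (all q = 0): capacity estimate degenerates to 0")

    def model(cc, k, s):
        return k * cc * s / (1.0 + k * cc)

    k0 = 1.0 / max(float(np.median(c[c > 0])), np.finfo(float).tiny)
    s0 = 1.1 * float(np.max(q))
    try:
        popt, pcov = curve_fit(
            model, c, q, p0=(k0, s0),
            bounds=((0.0, 0.0), (np.inf, np.inf)),
            max_nfev=max_nfev,
        )
    except RuntimeError as exc:  # scipy signals non-convergence this way
        raise FitFailureError(f"Langmuir fit did not converge: {exc}") from exc
    resid = q - model(c, *popt)
    if not (popt[0] > 0 and popt[1] > 0):
        raise FitFailureError(f"fit collapsed to a boundary: K={popt[0]:g}, S={popt[1]:g}")
    return LangmuirFit(
        params=LangmuirParameters(keq=float(popt[0]), scwm=float(popt[1])),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
        n_points=len(c),
        covariance=pcov,
    )
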