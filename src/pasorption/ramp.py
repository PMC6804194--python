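"""Sequential temperature-ramp desorption simulation.

The bench experiment equilibrates a PA solution with CWM at 15 degC, then
re-equilibrates at 22.5, 30 and 35 degC at fixed ethanol, sampling the
supernatant at each hold.  ``simulate_ramp`` reproduces that protocol under
three reversibility assumptions:

``equilibrium``
    Full reversibility: every step is an independent Langmuir batch
    equilibrium at (T_step, E).
``empirical``
    Step-1 is an equilibrium solve; later steps release user-supplied
    fractions of the step-1 adsorbed mass (e.g. measured desorption
    fractions), bypassing the isotherm.
``partial``
    A fraction ``phi`` of the step-1 adsorbed PA is irreversibly bound; the
    reversible remainder re-equilibrates at each step.

Hold durations are metadata only: each step is treated as having reached
equilibrium, so within-hold kinetics are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .sorption import (
    BatchSystem,
    Condition,
    EquilibriumState,
    RationalSurfaceCoefficients,
    DEFAULT_KEQ_COEFFS,
    DEFAULT_SCWM_COEFFS,
    langmuir_parameters,
    solve_batch_equilibrium,
)
from .errors import UndefinedBaselineError

__all__ = ["RampSchedule", "RampResult", "simulate_ramp", "percent_desorption_series"]

#: The bench protocol's temperature sequence (degC).
DEFAULT_RAMP_TEMPERATURES_C = (15.0, 22.5, 30.0, 35.0)


@dataclass(frozen=True)
class RampSchedule:
    """Ordered temperature steps at a fixed ethanol level.

    ``hold_minutes`` is carried as metadata (the simulator treats each step
    as an attained equilibrium regardless of hold length).
    """

    ethanol_pct: float
    temperatures_C: tuple[float, ...] = DEFAULT_RAMP_TEMPERATURES_C
    hold_minutes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.ethanol_pct < 0:
            raise ValueError("ethanol_pct must be >= 0")
        if len(self.temperatures_C) < 1:
            raise ValueError("schedule needs at least one temperature step")
        temps = self.temperatures_C
        if any(b <= a for a, b in zip(temps, temps[1:])):
            warnings.warn(
                "ramp temperatures are not strictly increasing; desorption "
                "percentages may not be monotone",
                UserWarning,
                stacklevel=2,
            )

    def conditions(self) -> list[Condition]:
        return [Condition.from_celsius(t, self.ethanol_pct) for t in self.temperatures_C]


@dataclass(frozen=True)
class RampResult:
    """Per-step equilibria and desorption percentages of one ramp."""

    schedule: RampSchedule
    states: tuple[EquilibriumState, ...]
    percent_desorption: tuple[float, ...]
    mode: str
    system: BatchSystem = field(repr=False, default=None)

    @property
    def adsorbed_series_mg(self) -> tuple[float, ...]:
        return tuple(s.adsorbed_mg for s in self.states)

    @property
    def dissolved_series_mg_per_L(self) -> tuple[float, ...]:
        return tuple(s.c_pa_mg_per_L for s in self.states)


def _desorption_percent(adsorbed: list[float]) -> list[float]:
    base = adsorbed[0]
    if base <= 0:
        raise UndefinedBaselineError("no PA adsorbed at step 1: percent desorption undefined")
    return [100.0 * (base - a) / base for a in adsorbed]


def simulate_ramp(
    system: BatchSystem,
    schedule: RampSchedule,
    keq_coeffs: RationalSurfaceCoefficients = DEFAULT_KEQ_COEFFS,
    scwm_coeffs: RationalSurfaceCoefficients = DEFAULT_SCWM_COEFFS,
    *,
    mode: str = "equilibrium",
    fractions: list[float] | None = None,
    phi: float | None = None,
    withdrawal_uL: float = 0.0,
) -> RampResult:
    """Simulate the sequential-equilibrium desorption ramp.

    Parameters
    ----------
    system : BatchSystem
        The closed liquid-solid system (volume, CWM mass, total PA).
    schedule : RampSchedule
        Temperature steps (degC) and fixed ethanol level.
    mode : {"equilibrium", "empirical", "partial"}
        Reversibility assumption (module docstring).
    fractions : list of float, optional
        ``empirical`` mode only: desorption fraction of the step-1 adsorbed
        mass for every step after the first (one per step, each in [0, 1]).
    phi : float, optional
        ``partial`` mode only: irreversibly bound fraction of the step-1
        adsorbed mass, in [0, 1].
    withdrawal_uL : float
        Supernatant aliquot removed after each step's sampling (depletes both
        volume and total PA for subsequent steps).  Default 0 treats the
        system as closed; the bench aliquot is small against the working
        volume, but the option makes that approximation testable.

    Notes
    -----
    In ``partial`` mode the irreversible pool ``phi * adsorbed(1)`` is
    removed from the total and the adsorbent mass is scaled by ``(1 - phi)``
    before the per-step solves.  This construction is self-consistent: at the
    step-1 condition it returns the step-1 state exactly, ``phi = 0``
    coincides with ``equilibrium`` mode, and ``phi = 1`` freezes the system.
    """
    conditions = schedule.conditions()
    if withdrawal_uL < 0:
        raise ValueError("withdrawal_uL must be >= 0")
    withdrawal_L = withdrawal_uL * 1e-6

    def params_at(cond: Condition):
        return langmuir_parameters(cond, keq_coeffs, scwm_coeffs)

    # step 1: equilibrium at the initial condition in every mode
    state1 = solve_batch_equilibrium(system, params_at(conditions[0]))
    states = [state1]
    volume = system.liquid_volume_L
    total = system.total_pa_mg

    if mode == "equilibrium" or mode == "partial":
        if mode == "partial":
            if phi is None or not 0.0 <= phi <= 1.0:
                raise ValueError(f"partial mode requires 0 <= phi <= 1, got {phi}")
            frozen_mg = phi * state1.adsorbed_mg
            cwm = system.cwm_mass_mg * (1.0 - phi)
        else:
            frozen_mg = 0.0
            cwm = system.cwm_mass_mg
        for cond in conditions[1:]:
            if withdrawal_L:
                removed = states[-1].c_pa_mg_per_L * withdrawal_L
                volume = max(volume - withdrawal_L, 0.0)
                total -= removed
            sub = BatchSystem(volume, cwm, max(total - frozen_mg, 0.0))
            st = solve_batch_equilibrium(sub, params_at(cond))
            if frozen_mg:
                adsorbed = st.adsorbed_mg + frozen_mg
                q = adsorbed / system.cwm_mass_mg if system.cwm_mass_mg else 0.0
                st = EquilibriumState(st.c_pa_mg_per_L, q, adsorbed, st.mass_residual)
            states.append(st)
    elif mode == "empirical":
        n_later = len(conditions) - 1
        if fractions is None or len(fractions) != n_later:
            raise ValueError(
                f"empirical mode requires one fraction per step after the first "
                f"({n_later}), got {fractions!r}"
            )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError(f"empirical fractions must lie in [0, 1], got {fractions}")
        for f in fractions:
            adsorbed = state1.adsorbed_mg * (1.0 - f)
            q = adsorbed / system.cwm_mass_mg if system.cwm_mass_mg else 0.0
            c = (system.total_pa_mg - adsorbed) / system.liquid_volume_L
            states.append(EquilibriumState(c, q, adsorbed, 0.0))
    else:
        raise ValueError(f"unknown mode {mode!r}; expected equilibrium, empirical or partial")

    percent = _desorption_percent([s.adsorbed_mg for s in states])
    return RampResult(
        schedule=schedule,
        states=tuple(states),
        percent_desorption=tuple(percent),
        mode=mode,
        system=system,
    )


def percent_desorption_series(result: RampResult) -> list[float]:
    """Percent desorption at each step relative to the step-1 bound mass.

    %des(k) = 100 * (adsorbed(1) - adsorbed(k)) / adsorbed(1).  Negative
    values (net further adsorption) are reported as-is, not clipped.
    """
    return _desorption_percent(list(result.adsorbed_series_mg))
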