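"""Ferric-chloride assay quantification of PA in catechin units.

The total iron-reactive phenolics assay reads a sample twice at 510 nm: once
after mixing with resuspension buffer (background phenolics) and once after
adding the ferric chloride reagent.  Concentration in mg catechin units
(C.U.) per L is obtained against a (+)-catechin calibration line and scaled
by the sample-to-cuvette dilution.

The two reads happen at different total cuvette volumes (the reagent is added
between them), so the background absorbance is rescaled by the volume ratio
before subtraction; the default geometry is 75 uL sample + 800 uL buffer +
125 uL reagent, i.e. dilution 1000/75 and background scale 875/1000.  Both
are configurable on :class:`AssayCalibration`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NegativeAdsorptionWarning, NegativeConcentrationWarning

__all__ = [
    "AssayCalibration",
    "AbsorbanceReading",
    "DEFAULT_DILUTION_FACTOR",
    "DEFAULT_BACKGROUND_SCALE",
    "build_calibration",
    "concentration_from_absorbance",
    "absorbance_from_concentration",
    "adsorbed_per_mg",
]

#: 75 uL sample brought to 1000 uL final cuvette volume.
DEFAULT_DILUTION_FACTOR = 1000.0 / 75.0
#: Background read at 875 uL rescaled to the 1000 uL final volume.
DEFAULT_BACKGROUND_SCALE = 875.0 / 1000.0


@dataclass(frozen=True)
class AssayCalibration:
    """Catechin calibration line plus cuvette geometry.

    slope : absorbance per (mg C.U./L) at cuvette concentration.
    intercept : absorbance at zero concentration.
    dilution_factor : sample-to-cuvette dilution (>= 1).
    background_scale : factor applied to the background read before
        subtraction (volume-consistent correction for the pre-reagent read).
    r_squared : coefficient of determination of the calibration fit.
    """

    slope: float
    intercept: float = 0.0
    dilution_factor: float = DEFAULT_DILUTION_FACTOR
    background_scale: float = DEFAULT_BACKGROUND_SCALE
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution_factor must be >= 1, got {self.dilution_factor}")


@dataclass(frozen=True)
class AbsorbanceReading:
    """Paired 510 nm reads: background (pre-reagent) and final (post-reagent)."""

    a_background: float
    a_final: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a_background) and np.isfinite(self.a_final)):
            raise ValueError("absorbance reads must be finite")
        if self.a_final < 0:
            raise ValueError(f"a_final must be >= 0, got {self.a_final}")


def build_calibration(
    standards,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    background_scale: float = DEFAULT_BACKGROUND_SCALE,
) -> AssayCalibration:
    """Ordinary least-squares calibration line from (concentration, absorbance) standards."""
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, absorbance) standards")
    conc, absorb = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("singular design: calibration standards need >= 2 distinct concentrations")
    fit = stats.linregress(conc, absorb)
    return AssayCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        dilution_factor=dilution_factor,
        background_scale=background_scale,
        r_squared=float(fit.rvalue**2),
    )


def concentration_from_absorbance(reading: AbsorbanceReading, cal: AssayCalibration) -> float:
    """PA concentration (mg C.U./L) in the undiluted sample.

    C = dilution * ((a_final - scale * a_background) - intercept) / slope.
    Negative results (noise near blank) are floored at zero with a warning.
    """
    net = reading.a_final - cal.background_scale * reading.a_background
    conc = cal.dilution_factor * (net - cal.intercept) / cal.slope
    if conc < 0:
        warnings.warn(
            f"negative concentration {conc:.4g} mg/L floored at 0",
            NegativeConcentrationWarning,
            stacklevel=2,
        )
        return 0.0
    return conc


def absorbance_from_concentration(
    conc_mg_per_L: float, cal: AssayCalibration, a_background: float = 0.0
) -> AbsorbanceReading:
    """Invert the calibration: the final read that a given concentration produces.

    Used by the synthetic-data generator; exact inverse of
    :func:`concentration_from_absorbance` at zero noise.
    """
    if conc_mg_per_L < 0:
        raise ValueError("conc_mg_per_L must be >= 0")
    a_final = (
        cal.slope * conc_mg_per_L / cal.dilution_factor
        + cal.intercept
        + cal.background_scale * a_background
    )
    return AbsorbanceReading(a_background=a_background, a_final=a_final)


def adsorbed_per_mg(
    control_mean_mg_per_L: float,
    trial_mg_per_L: float,
    volume_L: float,
    cwm_mass_mg: float,
) -> float:
    """Adsorbed PA per mg CWM from the control-trial concentration difference.

    q = (control_mean - trial) * V / m.  A negative result (trial above
    control, i.e. net release) is reported as-is with a warning.
    """
    if cwm_mass_mg <= 0:
        raise ZeroDivisionError(
            f"cwm_mass_mg must be > 0 to express adsorption per mg, got {cwm_mass_mg}"
        )
    q = (control_mean_mg_per_L - trial_mg_per_L) * volume_L / cwm_mass_mg
    if q < 0:
        warnings.warn(
            f"trial concentration exceeds control mean (q = {q:.4g} mg/mg)",
            NegativeAdsorptionWarning,
            stacklevel=2,
        )
    return q
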