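"""Proanthocyanidin compositional metrics.

Phloroglucinolysis cleaves PA interflavan bonds in the presence of excess
phloroglucinol: extension subunits are released as phloroglucinol adducts
and terminal subunits as free flavan-3-ols.  The ratio of total to terminal
subunit moles gives the mean degree of polymerization (mDP); the subunit
speciation gives % galloylation (gallate-ester subunits, e.g. epicatechin
gallate) and % gallo units (trihydroxylated B-rings, e.g. epigallocatechin),
and the mole-weighted subunit mass times mDP gives the average polymer
molecular weight (aMW).

Gel permeation chromatography (GPC) provides an orthogonal size measure: the
molar mass at a chosen cumulative-mass quantile (here accumulated from low
to high molar mass, so the 90 % quantile characterizes the high-MW tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPECIES",
    "GALLOYLATED_SPECIES",
    "GALLO_SPECIES",
    "DEFAULT_MW",
    "SubunitProfile",
    "GPCTrace",
    "mdp",
    "percent_galloylation",
    "percent_gallo",
    "average_mw",
    "molar_mass_at_quantile",
]

#: Flavan-3-ol subunit species tracked by the phloroglucinolysis assay.
SPECIES = ("catechin", "epicatechin", "epicatechin_gallate", "epigallocatechin")
#: Species bearing a gallate ester group.
GALLOYLATED_SPECIES = frozenset({"epicatechin_gallate"})
#: Species with a trihydroxylated B-ring.
GALLO_SPECIES = frozenset({"epigallocatechin"})

#: Free flavan-3-ol monoisotopic-free molecular weights, g/mol.
DEFAULT_MW = {
    "catechin": 290.27,
    "epicatechin": 290.27,
    "epicatechin_gallate": 442.37,
    "epigallocatechin": 306.27,
}

POSITIONS = ("terminal", "extension")


@dataclass(frozen=True)
class SubunitProfile:
    """Subunit amounts (nmol) per species and position.

    ``amounts`` maps (species, position) -> nmol, species from
    :data:`SPECIES`, position "terminal" (released free) or "extension"
    (phloroglucinol adduct).  Missing keys count as zero.  ``mw`` maps
    species -> molar mass (g/mol); the default uses free flavan-3-ol masses
    with no interflavan-bond or adduct correction.
    """

    amounts: dict
    mw: dict = field(default_factory=lambda: dict(DEFAULT_MW))

    def __post_init__(self) -> None:
        for key, nmol in self.amounts.items():
            species, position = key
            if species not in SPECIES:
                raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
            if position not in POSITIONS:
                raise ValueError(f"unknown position {position!r}; expected one of {POSITIONS}")
            if nmol < 0:
                raise ValueError(f"negative amount for {key}: {nmol}")
        for species in {k[0] for k in self.amounts}:
            if species not in self.mw:
                raise ValueError(f"no molecular weight for species {species!r}")

    def moles(self, position: str | None = None, species=None) -> float:
        """Total nmol, optionally filtered by position and/or species set."""
        return sum(
            nmol
            for (sp, pos), nmol in self.amounts.items()
            if (position is None or pos == position)
            and (species is None or sp in species)
        )


def mdp(profile: SubunitProfile) -> float:
    """Mean degree of polymerization: total subunit moles per terminal mole."""
    terminal = profile.moles("terminal")
    if terminal <= 0:
        raise ZeroDivisionError("mDP undefined: no terminal subunits in profile")
    return profile.moles() / terminal


def percent_galloylation(profile: SubunitProfile) -> float:
    """Percent of subunit moles bearing a gallate ester."""
    total = profile.moles()
    if total <= 0:
        raise ZeroDivisionError("empty profile: percent galloylation undefined")
    return 100.0 * profile.moles(species=GALLOYLATED_SPECIES) / total


def percent_gallo(profile: SubunitProfile) -> float:
    """Percent of subunit moles with a trihydroxylated B-ring."""
    total = profile.moles()
    if total <= 0:
        raise ZeroDivisionError("empty profile: percent gallo undefined")
    return 100.0 * profile.moles(species=GALLO_SPECIES) / total


def average_mw(profile: SubunitProfile) -> float:
    """Average polymer molecular weight: mDP x mole-weighted subunit mass (g/mol)."""
    total = profile.moles()
    if total <= 0:
        raise ZeroDivisionError("empty profile: average MW undefined")
    mean_subunit = (
        sum(nmol * profile.mw[sp] for (sp, _), nmol in profile.amounts.items()) / total
    )
    return mdp(profile) * mean_subunit


@dataclass(frozen=True)
class GPCTrace:
    """A GPC elution trace with its molar-mass calibration.

    ``elution_mL``/``signal`` are the ordered chromatogram samples (signal is
    a mass-proportional detector response, >= 0).  ``cal_elution_mL`` /
    ``cal_log10_mw`` define the column calibration, monotone decreasing in
    elution volume (large molecules elute first).
    """

    elution_mL: np.ndarray
    signal: np.ndarray
    cal_elution_mL: np.ndarray
    cal_log10_mw: np.ndarray

    def __post_init__(self) -> None:
        for name in ("elution_mL", "signal", "cal_elution_mL", "cal_log10_mw"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.elution_mL.size == 0 or self.elution_mL.size != self.signal.size:
            raise ValueError("elution_mL and signal must be non-empty and equal length")
        if np.any(self.signal < 0):
            raise ValueError("signal must be >= 0")
        if np.any(np.diff(self.elution_mL) <= 0):
            raise ValueError("elution_mL must be strictly increasing")
        if self.cal_elution_mL.size < 2 or self.cal_elution_mL.size != self.cal_log10_mw.size:
            raise ValueError("calibration needs >= 2 (elution, log10 MW) pairs")
        if np.any(np.diff(self.cal_elution_mL) <= 0):
            raise ValueError("calibration elution volumes must be strictly increasing")
        if np.any(np.diff(self.cal_log10_mw) >= 0):
            raise ValueError("calibration must be monotone decreasing in elution volume")

    def log10_mw_at(self, elution_mL) -> np.ndarray:
        """Interpolate the calibration at given elution volumes."""
        return np.interp(elution_mL, self.cal_elution_mL, self.cal_log10_mw)


def molar_mass_at_quantile(trace: GPCTrace, quantile: float = 0.9) -> float:
    """Molar mass (g/mol) at a cumulative-mass quantile of a GPC trace.

    Mass is accumulated from low to high molar mass (reverse elution order);
    the returned MW is where the cumulative mass fraction first reaches
    ``quantile``, linearly interpolated between samples.  The default 0.9
    characterizes the high-MW tail of the distribution.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    total = float(np.sum(trace.signal))
    if total <= 0:
        raise ValueError("all-zero signal: cumulative mass distribution undefined")
    mw = 10.0 ** trace.log10_mw_at(trace.elution_mL)
    if mw.size == 1:  # monodisperse: all mass at one molar mass
        return float(mw[0])
    # per-sample mass weights: signal x local elution spacing (trapezoid-like)
    spacing = np.gradient(trace.elution_mL)
    weights = trace.signal * spacing
    order = np.argsort(mw, kind="stable")
    mw_sorted = mw[order]
    cum = np.cumsum(weights[order])
    cumfrac = cum / cum[-1]
    if mw_sorted.size == 1:
        return float(mw_sorted[0])
    idx = int(np.searchsorted(cumfrac, quantile, side="left"))
    if idx == 0:
        return float(mw_sorted[0])
    if idx >= cumfrac.size:
        return float(mw_sorted[-1])
    f0, f1 = cumfrac[idx - 1], cumfrac[idx]
    m0, m1 = mw_sorted[idx - 1], mw_sorted[idx]
    if f1 == f0:
        return float(m1)
    return float(m0 + (quantile - f0) / (f1 - f0) * (m1 - m0))
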