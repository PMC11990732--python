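"""Van't Hoff thermodynamics, Gibbs energy and docking-energy post-processing.

The temperature dependence of the binding constant,

    ln Ka = -dH0/(R T) + dS0/R,

is fitted by OLS of ln Ka on 1/T: the slope gives the standard enthalpy change
dH0 and the intercept the entropy change dS0.  The Gibbs energy follows either
from dG0 = dH0 - T dS0 (the default here, self-consistent with the fitted
pair) or directly from dG0 = -R T ln Ka; the two differ only by the fit
residual at each temperature.

The sign pattern of (dH0, dS0) identifies the dominant intermolecular force:
both positive -> hydrophobic (entropy-driven, endothermic), both negative ->
van der Waals / hydrogen bonding, dH0 near zero with dS0 > 0 -> electrostatic.

Docking post-processing converts a docking score in kcal/mol to kJ/mol
(thermochemical calorie, factor 4.184) and to the implied inhibition constant
K_i = exp(dG/(R T)), a concentration in mol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "KCAL_TO_KJ",
    "ThermoResult",
    "DockingRecord",
    "vant_hoff_fit",
    "gibbs_from_Ka",
    "ka_from_thermo",
    "interpret_forces",
    "docking_postprocess",
]

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Thermochemical calorie conversion, kJ per kcal.
KCAL_TO_KJ = 4.184

#: |dH| below this (J/mol) counts as "approximately zero" for the
#: electrostatic-force rule; configurable in :func:`interpret_forces`.
ELECTROSTATIC_DH_TOL = 4000.0


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff fit: dH0, dS0 and per-temperature dG0."""

    delta_H: float  # J/mol
    delta_S: float  # J/(mol K)
    delta_G_per_T: dict  # K -> J/mol
    R_squared: float
    mode: str  # "from_HS" | "from_lnKa"
    force_interpretation: str


@dataclass(frozen=True)
class DockingRecord:
    """A docking free energy with its unit conversions and implied K_i."""

    delta_G_kcal: float
    delta_G_kJ: float
    K_i: float  # mol/L
    temperature: float  # K
    site_label: str = ""


def interpret_forces(
    delta_H: float,
    delta_S: float,
    dh_tol: float = ELECTROSTATIC_DH_TOL,
) -> str:
    """Map the (dH0, dS0) sign pattern to the dominant binding force.

    The "dH approximately 0" band for electrostatics is |dH| < ``dh_tol``
    (J/mol) and takes precedence over the sign rules inside that band, so
    every (dH, dS) pair maps to exactly one interpretation.
    """
    if abs(delta_H) < dh_tol and delta_S > 0:
        return "electrostatic"
    if delta_H > 0 and delta_S > 0:
        return "hydrophobic"
    if delta_H < 0 and delta_S < 0:
        return "vdw_or_hbond"
    return "other"


def vant_hoff_fit(
    Ka_by_T: Mapping[float, float],
    R: float = GAS_CONSTANT,
    dh_tol: float = ELECTROSTATIC_DH_TOL,
) -> ThermoResult:
    """OLS of ln Ka on 1/T; dH0 = -R*slope, dS0 = R*intercept.

    dG0 at each input temperature is computed as dH0 - T dS0 (mode
    ``from_HS``), which reproduces the fitted line exactly; the direct
    -R T ln Ka route is available via :func:`gibbs_from_Ka`.
    """
    temps = np.array(sorted(Ka_by_T), dtype=float)
    if temps.size < 2:
        raise ValueError("van't Hoff fit needs >= 2 distinct temperatures")
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive (K)")
    ka = np.array([Ka_by_T[t] for t in temps], dtype=float)
    if np.any(ka <= 0):
        raise ValueError("all Ka must be positive")
    x = 1.0 / temps
    y = np.log(ka)
    if temps.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = fit.slope, fit.intercept
        r2 = float(fit.rvalue**2) if not np.allclose(y, y[0]) else 1.0
    dH = -R * float(slope)
    dS = R * float(intercept)
    dG = {float(t): dH - t * dS for t in temps}
    return ThermoResult(
        delta_H=dH,
        delta_S=dS,
        delta_G_per_T=dG,
        R_squared=float(r2),
        mode="from_HS",
        force_interpretation=interpret_forces(dH, dS, dh_tol),
    )


def gibbs_from_Ka(Ka: float, T: float, R: float = GAS_CONSTANT) -> float:
    """dG0 = -R T ln Ka, in J/mol."""
    if Ka <= 0 or T <= 0:
        raise ValueError("Ka and T must be positive")
    return -R * T * math.log(Ka)


def ka_from_thermo(delta_H: float, delta_S: float, T: float, R: float = GAS_CONSTANT) -> float:
    """Binding constant implied by (dH0, dS0) at temperature T (L/mol)."""
    if T <= 0:
        raise ValueError("T must be positive")
    return math.exp(-delta_H / (R * T) + delta_S / R)


def docking_postprocess(
    delta_G_kcal: float,
    T: float,
    site_label: str = "",
    R: float = GAS_CONSTANT,
) -> DockingRecord:
    """Convert a docking energy to kJ/mol and the implied K_i = exp(dG/RT).

    A positive dG is allowed and simply yields K_i > 1 M.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    dg_kj = KCAL_TO_KJ * delta_G_kcal
    ki = math.exp(dg_kj * 1000.0 / (R * T))
    return DockingRecord(
        delta_G_kcal=delta_G_kcal,
        delta_G_kJ=dg_kj,
        K_i=ki,
        temperature=T,
        site_label=site_label,
    )
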