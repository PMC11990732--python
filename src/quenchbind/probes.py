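"""Conformational probes: synchronous-fluorescence shifts and UV trend.

Synchronous scans fix the offset between excitation and emission wavelengths;
an offset of 15 nm reports on tyrosine environments, 60 nm on tryptophan.  A
shift of the band maximum as ligand is titrated signals a polarity change
around those residues: red (toward longer wavelength) means a more polar, blue
a more hydrophobic environment.  Shifts of 1-2 nm on a ~1 nm grid are
meaningful, so peaks are located by parabolic interpolation.

The UV absorbance trend at the aromatic band is a mechanism cross-check: a
rising ground-state absorbance with ligand supports complex formation (static
quenching), a flat one supports purely collisional (dynamic) quenching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import TitrationSeries, parabolic_peak

__all__ = ["ShiftResult", "UvTrend", "synchronous_shift", "uv_trend"]

#: Peak shifts smaller than this (nm) are reported as "none".
DEFAULT_SHIFT_TOL = 0.5

PROBE_LABELS = {15: "Tyr environment", 60: "Trp environment"}


@dataclass(frozen=True)
class ShiftResult:
    """Peak trajectory of a synchronous-scan titration."""

    delta_lambda_mode: float  # nm offset of the scan (15 or 60)
    probe_label: str
    peak_by_conc: dict  # quencher conc mol/L -> peak wavelength nm
    net_shift: float  # nm, final minus initial
    direction: str  # "red" | "blue" | "none"
    intensity_drop_fraction: float  # 1 - F_last/F_first at the peaks


@dataclass(frozen=True)
class UvTrend:
    """Sign of the ground-state absorbance trend with ligand concentration."""

    verdict: str  # "increasing" | "decreasing" | "flat"
    slope: float  # OD per (mol/L)
    supports: str  # mechanism the trend is evidence for


def synchronous_shift(
    series: TitrationSeries,
    delta_lambda: float,
    shift_tolerance: float = DEFAULT_SHIFT_TOL,
) -> ShiftResult:
    """Track the interpolated band maximum across a synchronous titration.

    Raises on flat spectra (no identifiable peak above the noise floor,
    judged as peak prominence below 1% of the maximum intensity).
    """
    peaks: dict[float, float] = {}
    peak_int: list[float] = []
    for s in series.spectra:
        span = float(np.ptp(s.intensities))
        if span <= 1e-9 * max(float(np.max(s.intensities)), 1e-300) or span == 0.0:
            raise ValueError(
                f"flat spectrum at quencher_conc={s.quencher_conc:g}: no identifiable peak"
            )
        wl, inten = parabolic_peak(s.wavelengths, s.intensities)
        peaks[float(s.quencher_conc)] = wl
        peak_int.append(inten)
    concs = sorted(peaks)
    net = peaks[concs[-1]] - peaks[concs[0]]
    if net < -shift_tolerance:
        direction = "blue"
    elif net > shift_tolerance:
        direction = "red"
    else:
        direction = "none"
    return ShiftResult(
        delta_lambda_mode=float(delta_lambda),
        probe_label=PROBE_LABELS.get(int(delta_lambda), f"delta-lambda {delta_lambda:g} nm"),
        peak_by_conc=peaks,
        net_shift=float(net),
        direction=direction,
        intensity_drop_fraction=float(1.0 - peak_int[-1] / peak_int[0]),
    )


def uv_trend(
    concentrations,
    absorbances,
    flat_tol: float = 1e-3,
) -> UvTrend:
    """Classify the absorbance-vs-concentration trend at a fixed wavelength.

    OLS slope of OD on concentration; the verdict is "flat" when the
    predicted OD change across the titrated range is below ``flat_tol``
    (absolute OD units), otherwise the sign of the slope decides.
    """
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(absorbances, dtype=float)
    if conc.size < 3:
        raise ValueError("UV trend needs >= 3 concentrations")
    if conc.shape != od.shape:
        raise ValueError("concentrations and absorbances must have equal length")
    fit = stats.linregress(conc, od)
    slope = float(fit.slope)
    total_change = slope * float(np.ptp(conc))
    if abs(total_change) < flat_tol:
        verdict = "flat"
    elif slope > 0:
        verdict = "increasing"
    else:
        verdict = "decreasing"
    supports = {
        "increasing": "static (ground-state complex formation)",
        "flat": "dynamic (collisional quenching only)",
        "decreasing": "unassigned (atypical; check baseline/reference)",
    }[verdict]
    return UvTrend(verdict=verdict, slope=slope, supports=supports)
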