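"""Double-logarithm binding analysis and competitive site-marker displacement.

For static quenching the fraction of quenched fluorescence tracks complex
formation, giving the modified double-log relation

    log10((F0 - F)/F) = log10(Ka) + n * log10([Q] - [P](F0 - F)/F0)

whose intercept is the apparent binding constant Ka and slope the binding-site
number n.  The subtracted term [P](F0-F)/F0 corrects the known *total* ligand
concentration for the ligand sequestered in the complex, since the free
(equilibrium) concentration is not directly measurable.

Site assignment uses competitive displacement: refit Ka with a site-specific
marker pre-bound (warfarin for Sudlow site I, ibuprofen for site II); the
marker sharing the drug's pocket produces the larger drop in apparent Ka.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import QuenchCurve

__all__ = [
    "BindingResult",
    "DisplacementResult",
    "double_log_fit",
    "displacement_analysis",
]


@dataclass(frozen=True)
class BindingResult:
    """Apparent binding constant and site number from the double-log fit."""

    K_a: float  # L/mol
    log10_Ka: float
    log10_Ka_stderr: float
    n_sites: float
    n_stderr: float
    R_squared: float
    temperature: float  # K
    points_used: int
    points_dropped: int

    def __post_init__(self) -> None:
        if self.K_a <= 0:
            raise ValueError("K_a must be positive")
        if self.points_used < 3:
            raise ValueError("binding fit needs at least 3 usable points")


@dataclass(frozen=True)
class DisplacementResult:
    """Binary-vs-ternary Ka comparison and the resulting Sudlow-site call."""

    Ka_binary: float
    Ka_ternary_site1_marker: float
    Ka_ternary_site2_marker: float
    pct_reduction_site1: float
    pct_reduction_site2: float
    site_call: str  # "site_I" | "site_II" | "indeterminate"
    warning: str = ""


def double_log_fit(curve: QuenchCurve, protein_conc: float) -> BindingResult:
    """Fit log10((F0-F)/F) against log10 of the depletion-corrected [Q].

    Points whose log arguments are non-positive (no measurable quenching, or
    depletion correction exceeding the total ligand) are dropped and counted;
    at least 3 usable points must remain.  OLS gives slope n and intercept
    log10(Ka) with standard errors from the fit.
    """
    if protein_conc <= 0:
        raise ValueError("protein_conc must be > 0")
    conc = curve.concentrations
    F = curve.F
    F0 = curve.F0
    pos = conc > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 positive-concentration points")
    conc, F = conc[pos], F[pos]
    dF = F0 - F
    if np.all(dF <= 0):
        raise ValueError("no quenching signal: F >= F0 at every point")
    free_q = conc - protein_conc * dF / F0
    usable = (dF > 0) & (free_q > 0)
    dropped = int(conc.size - usable.sum())
    if usable.sum() < 3:
        raise ValueError(
            f"only {int(usable.sum())} usable points after dropping {dropped} "
            "with non-positive log arguments"
        )
    y = np.log10(dF[usable] / F[usable])
    x = np.log10(free_q[usable])
    fit = stats.linregress(x, y)
    return BindingResult(
        K_a=float(10.0**fit.intercept),
        log10_Ka=float(fit.intercept),
        log10_Ka_stderr=float(fit.intercept_stderr),
        n_sites=float(fit.slope),
        n_stderr=float(fit.stderr),
        R_squared=float(fit.rvalue**2),
        temperature=curve.temperature,
        points_used=int(usable.sum()),
        points_dropped=dropped,
    )


def percent_reduction(Ka_binary: float, Ka_ternary: float) -> float:
    """Percent drop in apparent Ka caused by a pre-bound site marker."""
    if Ka_binary <= 0:
        raise ValueError("Ka_binary must be positive")
    return 100.0 * (Ka_binary - Ka_ternary) / Ka_binary


def displacement_analysis(
    binary: BindingResult,
    ternary_site1: BindingResult,
    ternary_site2: BindingResult,
) -> DisplacementResult:
    """Compare binary and ternary binding constants and call the Sudlow site.

    The marker whose presence reduces Ka more strictly wins the call; equal
    reductions, or a Ka *increase* under both markers, are indeterminate (the
    latter with a warning, since negative displacement suggests a fit or
    labelling problem rather than genuine competition).
    """
    temps = {binary.temperature, ternary_site1.temperature, ternary_site2.temperature}
    if len(temps) != 1:
        raise ValueError("all three binding results must be at the same temperature")
    r1 = percent_reduction(binary.K_a, ternary_site1.K_a)
    r2 = percent_reduction(binary.K_a, ternary_site2.K_a)
    warning = ""
    if r1 < 0 and r2 < 0:
        warning = (
            "both ternary Ka exceed the binary Ka (negative displacement); "
            "no site assignment possible"
        )
        warnings.warn(warning, stacklevel=2)
        call = "indeterminate"
    elif r1 > r2:
        call = "site_I"
    elif r2 > r1:
        call = "site_II"
    else:
        call = "indeterminate"
    return DisplacementResult(
        Ka_binary=binary.K_a,
        Ka_ternary_site1_marker=ternary_site1.K_a,
        Ka_ternary_site2_marker=ternary_site2.K_a,
        pct_reduction_site1=r1,
        pct_reduction_site2=r2,
        site_call=call,
        warning=warning,
    )
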