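"""Synthetic titration generator with known ground truth.

No public instrument data exist for this kind of experiment, so every analysis
stage is validated against simulated titrations whose binding constants,
quenching mechanism, band shape and noise level are known exactly.

The static models are driven by mass-action equilibria:

* 1:1 binding P + Q <=> PQ, solved in closed form (stable quadratic branch);
* competitive binding P + Q <=> PQ, P + M <=> PM (a site marker M sharing the
  pocket), solved by bounded root-finding on free protein.

Fluorescence is a Gaussian emission band whose amplitude tracks free protein
(the ground-state complex is dark by default, ``complex_brightness = 0``);
the dynamic model instead divides the unquenched band by the Stern-Volmer
factor 1 + Ksv [Q].  Noise is multiplicative Gaussian on intensities, seeded.

Defaults mirror a typical serum-albumin titration: 1.6e-6 M protein, ligand
0 to 3.2e-6 M in 9 steps, emission band at 337 nm scanned 300-450 nm on a
1 nm grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .spectra import EmissionSpectrum, TitrationSeries
from .thermo import GAS_CONSTANT, ka_from_thermo

__all__ = [
    "SimConfig",
    "solve_equilibrium_1to1",
    "solve_equilibrium_competitive",
    "competitive_species",
    "simulate_titration",
    "simulate_multi_temperature",
]

MECHANISMS = ("static_1to1", "dynamic", "static_competitive")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one simulated titration.

    ``mechanism`` selects the quenching model; ``Ka_true`` drives the static
    models, ``Ksv_true`` the dynamic one, and ``marker_Ka``/``marker_conc``
    add a competing site marker for ``static_competitive``.  When
    ``temperatures`` with ``delta_H``/``delta_S`` are given,
    :func:`simulate_multi_temperature` derives Ka(T) from the van't Hoff
    relation Ka = exp(-dH/(R T) + dS/R).
    """

    mechanism: str = "static_1to1"
    Ka_true: float = 3.98e6  # L/mol
    Ksv_true: float = 2.51e5  # L/mol (dynamic mode)
    marker_Ka: float | None = None  # L/mol (competitive mode)
    marker_conc: float = 0.0  # mol/L
    protein_conc: float = 1.6e-6  # mol/L
    quencher_concs: tuple = tuple(np.linspace(0.0, 3.2e-6, 9))
    band_center: float = 337.0  # nm
    band_sigma: float = 25.0  # nm
    F0_amplitude: float = 1000.0  # a.u.
    complex_brightness: float = 0.0  # relative quantum yield of the complex
    noise_sigma_frac: float = 0.0  # multiplicative Gaussian noise, fraction
    baseline_noise: float = 0.0  # additive Gaussian noise, a.u.
    seed: int = 0
    temperature: float = 298.0  # K
    temperatures: tuple | None = None  # K, multi-temperature mode
    delta_H: float | None = None  # J/mol
    delta_S: float | None = None  # J/(mol K)
    excitation_nm: float = 295.0
    wl_min: float = 300.0
    wl_max: float = 450.0
    wl_step: float = 1.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        concs = tuple(float(c) for c in self.quencher_concs)
        object.__setattr__(self, "quencher_concs", concs)
        if any(c < 0 for c in concs) or 0.0 not in concs:
            raise ValueError("quencher_concs must be non-negative and include 0")
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be > 0")
        if self.noise_sigma_frac < 0 or self.baseline_noise < 0:
            raise ValueError("noise levels must be >= 0")
        if not (0.0 <= self.complex_brightness < 1.0):
            raise ValueError("complex_brightness must be in [0, 1)")
        if self.mechanism == "static_competitive" and self.marker_Ka is None:
            raise ValueError("static_competitive mode requires marker_Ka")


def solve_equilibrium_1to1(P_total: float, Q_total: float, Ka: float) -> float:
    """Complex concentration of P + Q <=> PQ at equilibrium (mol/L).

    The unique root in [0, min(P, Q)] of
    ``Ka x^2 - (Ka (P+Q) + 1) x + Ka P Q = 0``, evaluated on the numerically
    stable branch ``x = 2c / (b + sqrt(b^2 - 4 a c))`` (no cancellation for
    small or large Ka).
    """
    if P_total < 0 or Q_total < 0 or Ka < 0:
        raise ValueError("totals and Ka must be non-negative")
    if Ka == 0.0 or P_total == 0.0 or Q_total == 0.0:
        return 0.0
    b = Ka * (P_total + Q_total) + 1.0
    c = Ka * P_total * Q_total
    disc = b * b - 4.0 * Ka * c
    x = 2.0 * c / (b + math.sqrt(max(disc, 0.0)))
    return min(x, P_total, Q_total)


def competitive_species(
    P_total: float,
    Q_total: float,
    M_total: float,
    Ka_Q: float,
    Ka_M: float,
) -> dict:
    """All species of the coupled equilibria P+Q<=>PQ, P+M<=>PM (mol/L).

    Solved by bracketed root-finding on free protein p: given p, the free
    ligands are Q/(1 + Ka_Q p) and M/(1 + Ka_M p), and the protein mass
    balance residual is strictly increasing in p, so a root in [0, P_total]
    always exists and is unique.  Mass balances hold to ~1e-12 relative.
    """
    for v in (P_total, Q_total, M_total, Ka_Q, Ka_M):
        if v < 0:
            raise ValueError("all inputs must be non-negative")
    if M_total == 0.0 or Ka_M == 0.0:
        pq = solve_equilibrium_1to1(P_total, Q_total, Ka_Q)
        p_free = P_total - pq
        return {
            "P_free": p_free,
            "Q_free": Q_total - pq,
            "M_free": M_total,
            "PQ": pq,
            "PM": 0.0,
        }
    if P_total == 0.0:
        return {"P_free": 0.0, "Q_free": Q_total, "M_free": M_total, "PQ": 0.0, "PM": 0.0}

    def residual(p: float) -> float:
        bound = p * (
            Ka_Q * Q_total / (1.0 + Ka_Q * p) + Ka_M * M_total / (1.0 + Ka_M * p)
        )
        return p + bound - P_total

    if residual(P_total) <= 0:  # no binding at all (both Ka zero-ish)
        p_free = P_total
    else:
        p_free = brentq(residual, 0.0, P_total, xtol=1e-30, rtol=8.9e-16, maxiter=200)
    pq = Ka_Q * p_free * Q_total / (1.0 + Ka_Q * p_free)
    pm = Ka_M * p_free * M_total / (1.0 + Ka_M * p_free)
    return {
        "P_free": float(p_free),
        "Q_free": Q_total / (1.0 + Ka_Q * p_free),
        "M_free": M_total / (1.0 + Ka_M * p_free),
        "PQ": float(pq),
        "PM": float(pm),
    }


def solve_equilibrium_competitive(
    P_total: float,
    Q_total: float,
    M_total: float,
    Ka_Q: float,
    Ka_M: float,
) -> tuple[float, float]:
    """Complex concentrations ([PQ], [PM]) of the competitive equilibrium."""
    sp = competitive_species(P_total, Q_total, M_total, Ka_Q, Ka_M)
    return sp["PQ"], sp["PM"]


def _gaussian_band(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def simulate_titration(config: SimConfig) -> tuple[TitrationSeries, dict]:
    """Generate a titration series plus its ground-truth record.

    Static modes scale the emission band by
    ``([P_free] + complex_brightness * [complexes]) / P_total``; the dynamic
    mode divides the unquenched band by ``1 + Ksv [Q]``.  Multiplicative
    (and optional additive) Gaussian noise is applied with the config seed;
    identical configs give bit-identical output (numpy PCG64 generator).
    """
    rng = np.random.default_rng(config.seed)
    wl = np.arange(config.wl_min, config.wl_max + config.wl_step / 2, config.wl_step)
    band = config.F0_amplitude * _gaussian_band(wl, config.band_center, config.band_sigma)
    P = config.protein_conc
    spectra = []
    truth_species = []
    for q in config.quencher_concs:
        if config.mechanism == "static_1to1":
            pq = solve_equilibrium_1to1(P, q, config.Ka_true)
            pm = 0.0
            scale = ((P - pq) + config.complex_brightness * pq) / P
        elif config.mechanism == "static_competitive":
            pq, pm = solve_equilibrium_competitive(
                P, q, config.marker_conc, config.Ka_true, config.marker_Ka
            )
            scale = ((P - pq - pm) + config.complex_brightness * (pq + pm)) / P
        else:  # dynamic
            pq = pm = 0.0
            scale = 1.0 / (1.0 + config.Ksv_true * q)
        inten = band * scale
        if config.noise_sigma_frac > 0:
            inten = inten * (1.0 + config.noise_sigma_frac * rng.standard_normal(wl.size))
        if config.baseline_noise > 0:
            inten = inten + config.baseline_noise * rng.standard_normal(wl.size)
        inten = np.clip(inten, 0.0, None)
        spectra.append(
            EmissionSpectrum(
                wavelengths=wl,
                intensities=inten,
                excitation_wavelength=config.excitation_nm,
                temperature=config.temperature,
                quencher_conc=q,
            )
        )
        truth_species.append({"Q_total": q, "complex_PQ": pq, "complex_PM": pm})
    series = TitrationSeries(
        spectra=tuple(spectra),
        protein_conc=P,
        temperature=config.temperature,
        label=config.label,
    )
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "rng": "numpy.random.default_rng (PCG64)",
        "species": truth_species,
    }
    return series, truth


def simulate_multi_temperature(config: SimConfig) -> dict:
    """Simulate one titration per temperature with Ka(T) from (dH, dS).

    Returns ``{T: (TitrationSeries, truth)}``.  Requires ``temperatures``,
    ``delta_H`` and ``delta_S`` on the config; seeds are derived per
    temperature so replicates stay independent yet reproducible.
    """
    if config.temperatures is None or config.delta_H is None or config.delta_S is None:
        raise ValueError("multi-temperature mode needs temperatures, delta_H and delta_S")
    out = {}
    for i, T in enumerate(config.temperatures):
        ka = ka_from_thermo(config.delta_H, config.delta_S, T)
        cfg_t = SimConfig(
            **{
                **asdict(config),
                "quencher_concs": tuple(config.quencher_concs),
                "temperatures": None,
                "Ka_true": ka,
                "temperature": float(T),
                "seed": config.seed + i,
                "label": f"{config.label}_T{T:g}",
            }
        )
        out[float(T)] = simulate_titration(cfg_t)
    return out
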