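"""Emission-spectrum data model, titration I/O and inner-filter correction.

A fluorescence titration keeps the protein concentration fixed while the
quencher (ligand) concentration increases; each step yields one emission
spectrum.  The first spectrum, at zero quencher, defines the unquenched
intensity F0.  All downstream analyses consume either a :class:`TitrationSeries`
or the reduced :class:`QuenchCurve` (F0 and F at the emission maximum per
concentration).

Spectra are exchanged as delimited text (CSV/TSV): first column
``wavelength_nm``, one intensity column per quencher concentration, plus a
small YAML/JSON metadata record carrying concentrations, protein
concentration, temperature and excitation wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "QuenchCurve",
    "inner_filter_correct",
    "correct_series",
    "extract_quench_curve",
    "read_titration",
    "write_titration",
    "parabolic_peak",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission scan at a single quencher concentration.

    Parameters
    ----------
    wavelengths
        Emission wavelengths in nm, strictly increasing.
    intensities
        Fluorescence intensities (arbitrary units), finite and non-negative.
    excitation_wavelength
        Excitation wavelength in nm.
    temperature
        Sample temperature in K.
    quencher_conc
        Total quencher concentration in mol/L.
    absorbance_ex, absorbance_em
        Optional optical densities at the excitation and emission wavelengths,
        used by the inner-filter correction; ``None`` when not measured.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_wavelength: float
    temperature: float
    quencher_conc: float
    absorbance_ex: float | None = None
    absorbance_em: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.ndim != 1 or inten.shape != wl.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 3:
            raise ValueError("a spectrum needs at least 3 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.quencher_conc < 0:
            raise ValueError("quencher_conc must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if a is not None and a < 0:
                raise ValueError(f"{name} must be >= 0 (corrupt input?)")

    def intensity_at(self, wavelength: float) -> float:
        """Linearly interpolated intensity at ``wavelength`` (nm, within grid)."""
        if not (self.wavelengths[0] <= wavelength <= self.wavelengths[-1]):
            raise ValueError(
                f"wavelength {wavelength} nm outside grid "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        return float(np.interp(wavelength, self.wavelengths, self.intensities))


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration: spectra at ascending quencher concentration.

    All spectra share one wavelength grid, temperature and excitation
    wavelength; the first spectrum must be at zero quencher (it defines F0).
    """

    spectra: tuple[EmissionSpectrum, ...]
    protein_conc: float
    temperature: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "spectra", tuple(self.spectra))
        if len(self.spectra) < 2:
            raise ValueError("a titration needs at least 2 spectra (F0 + one point)")
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be > 0")
        first = self.spectra[0]
        if first.quencher_conc != 0:
            raise ValueError("first spectrum must be at zero quencher concentration")
        concs = [s.quencher_conc for s in self.spectra]
        if not all(b > a for a, b in zip(concs, concs[1:])):
            raise ValueError("spectra must be in strictly ascending quencher_conc order")
        for s in self.spectra[1:]:
            if not np.array_equal(s.wavelengths, first.wavelengths):
                raise ValueError("all spectra must share the same wavelength grid")
            if s.temperature != first.temperature:
                raise ValueError("all spectra must share the same temperature")
            if s.excitation_wavelength != first.excitation_wavelength:
                raise ValueError("all spectra must share the same excitation wavelength")
        if self.temperature != first.temperature:
            raise ValueError("series temperature must match its spectra")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.quencher_conc for s in self.spectra])

    @property
    def excitation_wavelength(self) -> float:
        return self.spectra[0].excitation_wavelength

    def has_absorbances(self) -> bool:
        return all(
            s.absorbance_ex is not None and s.absorbance_em is not None
            for s in self.spectra
        )


@dataclass(frozen=True)
class QuenchCurve:
    """Reduced titration data: F0 and F per quencher concentration.

    ``concentrations`` excludes or includes zero; when a zero point is present
    its F equals F0 by construction.
    """

    concentrations: np.ndarray
    F0: float
    F: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "F", f)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("concentrations and F must be 1-D and equal length")
        if self.F0 <= 0 or np.any(f <= 0):
            raise ValueError("intensities must be positive")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")


def inner_filter_correct(F_obs, A_ex, A_em):
    """Correct observed fluorescence for the inner-filter effect.

    Attenuation of the excitation beam and reabsorption of emitted light each
    scale the signal by ``10**(-A/2)`` on average over a 1 cm cuvette, so the
    corrected intensity is ``F_obs * 10**((A_ex + A_em) / 2)``.  Works
    element-wise on arrays.
    """
    F_obs = np.asarray(F_obs, dtype=float)
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(F_obs < 0):
        raise ValueError("F_obs must be >= 0")
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbances must be >= 0 (corrupt input?)")
    out = F_obs * 10.0 ** ((A_ex + A_em) / 2.0)
    return out if out.ndim else float(out)


def correct_series(series: TitrationSeries) -> TitrationSeries:
    """Apply the inner-filter correction to every spectrum of a series.

    Requires each spectrum to carry both absorbances; raises otherwise, since
    the correction is optional and simply skipped when absorbances were not
    recorded.
    """
    if not series.has_absorbances():
        raise ValueError("inner-filter correction requires absorbance_ex/em on every spectrum")
    corrected = tuple(
        replace(s, intensities=inner_filter_correct(s.intensities, s.absorbance_ex, s.absorbance_em))
        for s in series.spectra
    )
    return replace(series, spectra=corrected)


def parabolic_peak(wavelengths: np.ndarray, intensities: np.ndarray) -> tuple[float, float]:
    """Locate a band maximum by 3-point parabolic interpolation.

    Returns ``(wavelength, intensity)`` of the vertex of the parabola through
    the discrete argmax and its two neighbours; falls back to the grid point
    when the argmax sits on the boundary.  Sub-grid accuracy matters because
    band shifts of ~1-2 nm on a 1 nm grid are scientifically meaningful.
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(intensities, dtype=float)
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(wl[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:  # flat triple: no curvature
        return float(wl[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    # Uniform-grid vertex; for mildly non-uniform grids use local spacing.
    h = 0.5 * (wl[i + 1] - wl[i - 1])
    peak_wl = wl[i] + delta * h
    peak_y = y1 - 0.25 * (y0 - y2) * delta
    return float(peak_wl), float(peak_y)


def extract_quench_curve(
    series: TitrationSeries,
    mode: str = "peak",
    wavelength: float | None = None,
) -> QuenchCurve:
    """Reduce a titration series to F0 and F at a single wavelength.

    ``mode="peak"`` reads every spectrum at the interpolated emission maximum
    of the zero-quencher spectrum, held fixed across the titration so that all
    F/F0 ratios compare intensities at one wavelength.  ``mode="fixed"``
    (or ``"fixed-wavelength"``) reads at the user-supplied ``wavelength``.
    """
    if mode == "peak":
        wl_peak, _ = parabolic_peak(series.wavelengths, series.spectra[0].intensities)
    elif mode in ("fixed", "fixed-wavelength"):
        if wavelength is None:
            raise ValueError("fixed-wavelength mode requires a wavelength")
        wl_peak = float(wavelength)
        if not (series.wavelengths[0] <= wl_peak <= series.wavelengths[-1]):
            raise ValueError(f"wavelength {wl_peak} nm outside the spectral grid")
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'peak' or 'fixed'")
    F = np.array([s.intensity_at(wl_peak) for s in series.spectra])
    if F[0] <= 0:
        raise ValueError("zero-concentration spectrum has non-positive intensity at the read wavelength")
    return QuenchCurve(
        concentrations=series.concentrations,
        F0=float(F[0]),
        F=F,
        temperature=series.temperature,
    )


def _load_meta(meta) -> dict:
    if isinstance(meta, (str, Path)):
        with open(meta) as fh:
            meta = yaml.safe_load(fh)
    if not isinstance(meta, Mapping):
        raise ValueError("metadata must be a mapping or a path to a YAML/JSON file")
    return dict(meta)


def read_titration(path, meta) -> TitrationSeries:
    """Read a delimited-text titration (CSV or TSV) plus its metadata record.

    The file must have a wavelength column first (name containing
    "wavelength") and one intensity column per entry of
    ``meta["quencher_concs_M"]``, in ascending-concentration order.  ``meta``
    is a mapping or a path to a YAML/JSON file with keys ``protein_conc_M``,
    ``quencher_concs_M``, ``temperature_K``, ``excitation_nm`` and optionally
    ``absorbance_ex``/``absorbance_em`` (lists parallel to the
    concentrations) and ``label``.
    """
    meta = _load_meta(meta)
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("spectra file needs a wavelength column and at least one intensity column")
    wl_col = df.columns[0]
    if "wavelength" not in wl_col.lower():
        raise ValueError(f"first column {wl_col!r} is not a wavelength column")
    concs = [float(c) for c in meta["quencher_concs_M"]]
    n_int = df.shape[1] - 1
    if n_int != len(concs):
        raise ValueError(
            f"file has {n_int} intensity columns but metadata lists {len(concs)} concentrations"
        )
    wl = df[wl_col].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength column must be strictly increasing")
    a_ex = meta.get("absorbance_ex")
    a_em = meta.get("absorbance_em")
    spectra = []
    for j, conc in enumerate(concs):
        spectra.append(
            EmissionSpectrum(
                wavelengths=wl,
                intensities=df.iloc[:, j + 1].to_numpy(dtype=float),
                excitation_wavelength=float(meta["excitation_nm"]),
                temperature=float(meta["temperature_K"]),
                quencher_conc=conc,
                absorbance_ex=None if a_ex is None else float(a_ex[j]),
                absorbance_em=None if a_em is None else float(a_em[j]),
            )
        )
    return TitrationSeries(
        spectra=tuple(spectra),
        protein_conc=float(meta["protein_conc_M"]),
        temperature=float(meta["temperature_K"]),
        label=str(meta.get("label", "")),
    )


def series_meta(series: TitrationSeries) -> dict:
    """Metadata record for a series, suitable for :func:`read_titration`."""
    meta = {
        "protein_conc_M": series.protein_conc,
        "quencher_concs_M": [float(c) for c in series.concentrations],
        "temperature_K": series.temperature,
        "excitation_nm": series.excitation_wavelength,
        "label": series.label,
    }
    if series.has_absorbances():
        meta["absorbance_ex"] = [float(s.absorbance_ex) for s in series.spectra]
        meta["absorbance_em"] = [float(s.absorbance_em) for s in series.spectra]
    return meta


def write_titration(series: TitrationSeries, path, meta_path=None) -> None:
    """Write a series as CSV (wavelength_nm + one column per concentration).

    When ``meta_path`` is given, the matching metadata record is written there
    as YAML so the pair round-trips through :func:`read_titration`.
    """
    data = {"wavelength_nm": series.wavelengths}
    for j, s in enumerate(series.spectra):
        data[f"intensity_{j:02d}"] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            yaml.safe_dump(series_meta(series), fh)
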