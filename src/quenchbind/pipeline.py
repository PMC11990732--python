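"""Study orchestration: run the full analysis chain from a config file.

Stages run in dependency order — inner-filter correction, quench-curve
extraction, Stern-Volmer fits, mechanism call, double-log binding fits,
van't Hoff thermodynamics, optional marker displacement, synchronous-shift
analysis and docking post-processing.  Partial configs yield partial reports;
a stage that cannot run (missing inputs or an upstream failure) is recorded
with its reason instead of aborting the study.

The report is a plain JSON-serializable dict mirroring the usual tabular
presentation of such studies (per-temperature quenching and binding blocks,
one thermodynamics block, one displacement block), with provenance (input
hashes, config echo, package version) so every number is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .binding import BindingResult, displacement_analysis, double_log_fit
from .probes import synchronous_shift
from .quenching import DEFAULT_TAU0, DIFFUSION_LIMIT_KQ, classify_mechanism, stern_volmer_fit
from .spectra import correct_series, extract_quench_curve, read_titration
from .thermo import docking_postprocess, gibbs_from_Ka, vant_hoff_fit

__all__ = ["run_study", "load_config"]

log = logging.getLogger("quenchbind")


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _load_series(entry: Mapping, base: Path, hashes: dict):
    path = Path(entry["path"])
    if not path.is_absolute():
        path = base / path
    meta = entry.get("meta")
    if isinstance(meta, str):
        meta_path = Path(meta)
        if not meta_path.is_absolute():
            meta_path = base / meta_path
        hashes[str(meta_path)] = _sha256(meta_path)
        meta = meta_path
    series = read_titration(path, meta)
    hashes[str(path)] = _sha256(path)
    return series


def run_study(config, base_dir=None) -> dict:
    """Execute the configured analysis stages and return the study report.

    ``config`` is a mapping or a path to a YAML file.  Recognised keys:
    ``titrations`` (list of ``{path, meta}``, one per temperature),
    ``markers`` (``{site1: {...}, site2: {...}}`` ternary titrations),
    ``synchronous`` (list of ``{path, meta, delta_lambda}``),
    ``docking`` (list of ``{delta_G_kcal, temperature_K, site_label}``),
    plus options ``tau0_s``, ``kq_threshold``, ``mode``, ``wavelength``.
    Relative paths resolve against the config file's directory (or
    ``base_dir``).
    """
    t_start = time.time()
    if isinstance(config, (str, Path)) and base_dir is None:
        base_dir = Path(config).parent
    cfg = load_config(config)
    base = Path(base_dir) if base_dir is not None else Path.cwd()

    tau0 = float(cfg.get("tau0_s", DEFAULT_TAU0))
    kq_threshold = float(cfg.get("kq_threshold", DIFFUSION_LIMIT_KQ))
    mode = cfg.get("mode", "peak")
    wavelength = cfg.get("wavelength")

    hashes: dict[str, str] = {}
    warnings_list: list[str] = []
    errors: dict[str, str] = {}
    report: dict = {
        "quenching": {},
        "binding": {},
        "mechanism": None,
        "thermo": None,
        "displacement": None,
        "shifts": [],
        "docking": [],
    }

    # --- titrations -> quench curves -> Stern-Volmer + double-log fits
    curves = {}
    binding_by_T: dict[float, BindingResult] = {}
    sv_results = []
    for entry in cfg.get("titrations", []):
        try:
            series = _load_series(entry, base, hashes)
            if series.has_absorbances():
                series = correct_series(series)
            curve = extract_quench_curve(series, mode=mode, wavelength=wavelength)
            curves[series.temperature] = (curve, series.protein_conc)
        except Exception as exc:  # collect, keep going
            errors[f"titration:{entry.get('path')}"] = str(exc)
            continue
    for T, (curve, pconc) in sorted(curves.items()):
        t0 = time.time()
        try:
            sv = stern_volmer_fit(curve, tau0=tau0)
            sv_results.append(sv)
            report["quenching"][f"{T:g}"] = _asdict(sv)
        except Exception as exc:
            errors[f"quench:{T:g}"] = str(exc)
        try:
            b = double_log_fit(curve, pconc)
            binding_by_T[T] = b
            report["binding"][f"{T:g}"] = _asdict(b)
            if b.points_dropped:
                warnings_list.append(
                    f"binding fit at {T:g} K dropped {b.points_dropped} point(s) "
                    "with non-positive log arguments"
                )
        except Exception as exc:
            errors[f"bind:{T:g}"] = str(exc)
        log.info("temperature %g K analysed in %.3f s", T, time.time() - t0)

    # --- mechanism call
    if len(sv_results) >= 2:
        report["mechanism"] = _asdict(classify_mechanism(sv_results, kq_threshold=kq_threshold))
    else:
        errors.setdefault("mechanism", "skipped: >=2 temperatures required")

    # --- van't Hoff
    if len(binding_by_T) >= 2:
        thermo = vant_hoff_fit({T: b.K_a for T, b in binding_by_T.items()})
        block = _asdict(thermo)
        block["delta_G_from_lnKa_per_T"] = {
            f"{T:g}": gibbs_from_Ka(b.K_a, T) for T, b in binding_by_T.items()
        }
        report["thermo"] = block
    else:
        errors.setdefault("thermo", "skipped: >=2 temperatures required")

    # --- displacement
    markers = cfg.get("markers")
    if markers:
        try:
            tern = {}
            for site in ("site1", "site2"):
                series = _load_series(markers[site], base, hashes)
                if series.has_absorbances():
                    series = correct_series(series)
                curve = extract_quench_curve(series, mode=mode, wavelength=wavelength)
                tern[site] = double_log_fit(curve, series.protein_conc)
            binary = binding_by_T.get(tern["site1"].temperature)
            if binary is None:
                raise ValueError(
                    "no binary titration at the marker temperature "
                    f"{tern['site1'].temperature:g} K"
                )
            disp = displacement_analysis(binary, tern["site1"], tern["site2"])
            report["displacement"] = _asdict(disp)
            if disp.warning:
                warnings_list.append(disp.warning)
        except Exception as exc:
            errors["displacement"] = str(exc)

    # --- synchronous shifts
    for entry in cfg.get("synchronous", []):
        try:
            series = _load_series(entry, base, hashes)
            res = synchronous_shift(series, delta_lambda=float(entry["delta_lambda"]))
            report["shifts"].append(_asdict(res))
        except Exception as exc:
            errors[f"syncshift:{entry.get('path')}"] = str(exc)

    # --- docking post-processing
    for entry in cfg.get("docking", []):
        rec = docking_postprocess(
            float(entry["delta_G_kcal"]),
            float(entry.get("temperature_K", 298.0)),
            site_label=str(entry.get("site_label", "")),
        )
        report["docking"].append(_asdict(rec))

    # externally computed CD secondary-structure percentages are carried
    # through verbatim (no deconvolution is performed here)
    if "cd_helix_pct" in cfg:
        report["cd_helix_pct"] = _asdict(cfg["cd_helix_pct"])

    report["provenance"] = {
        "software": f"quenchbind {__version__}",
        "config": _asdict({k: v for k, v in cfg.items()}),
        "input_sha256": hashes,
        "tau0_s": tau0,
        "kq_threshold": kq_threshold,
    }
    report["warnings"] = warnings_list
    report["errors"] = errors
    log.info("study complete in %.3f s", time.time() - t_start)
    return report
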