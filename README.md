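# quenchbind

Analysis toolkit for fluorescence-quenching studies of small-molecule binding
to serum albumin (and other single-fluorophore proteins). It is aimed at
spectroscopists who titrate a ligand against a protein, watch the tryptophan
emission go down, and want defensible numbers out the other end: the
quenching mechanism, the binding constant and stoichiometry, the
thermodynamic driving forces, and the Sudlow-site assignment.

## What it computes

Given titration series F(λ) at fixed protein concentration [P] and increasing
ligand concentration [Q] (optionally inner-filter corrected by
F_cor = F_obs · 10^((A_ex + A_em)/2)):

* **Stern–Volmer quenching** — OLS fit of F₀/F = 1 + K_SV[Q]; the bimolecular
  rate constant K_q = K_SV/τ₀ (τ₀ ≈ 10 ns for albumin). K_SV falling with
  temperature and K_q above the diffusion limit (~2×10¹⁰ M⁻¹s⁻¹) classify the
  quenching as *static* (ground-state complex); the reverse pattern as
  *dynamic* (collisional).
* **Binding constant and stoichiometry** — the depletion-corrected double-log
  regression log₁₀((F₀−F)/F) = log₁₀K_a + n·log₁₀([Q] − [P](F₀−F)/F₀),
  where the subtracted term converts total to free ligand.
* **Van't Hoff thermodynamics** — ln K_a = −ΔH⁰/RT + ΔS⁰/R across ≥2
  temperatures; ΔG⁰ = ΔH⁰ − TΔS⁰; the (ΔH⁰, ΔS⁰) sign pattern names the
  dominant force (both positive → hydrophobic, both negative → van der
  Waals/H-bond, ΔH⁰ ≈ 0 with ΔS⁰ > 0 → electrostatic).
* **Site-marker displacement** — percent reduction of apparent K_a when
  warfarin (Sudlow site I) or ibuprofen (site II) pre-occupies a pocket;
  the larger reduction assigns the site.
* **Synchronous-fluorescence shifts** — sub-grid peak tracking of Δλ = 15 nm
  (Tyr) and Δλ = 60 nm (Trp) scans; blue/red calls with a 0.5 nm tolerance.
* **Docking post-processing** — kcal↔kJ conversion (4.184) and the implied
  inhibition constant K_i = exp(ΔG/RT).
* **Synthetic titrations** — a mass-action simulator (1:1, competitive, and
  collisional models; exact equilibrium solvers; seeded noise) providing
  ground truth for every estimator above.

## Worked example

```python
from quenchbind import (SimConfig, simulate_titration, extract_quench_curve,
                        double_log_fit, vant_hoff_fit, docking_postprocess)

# a noise-free 1:1 titration with known Ka, analysed blind
series, truth = simulate_titration(SimConfig(Ka_true=3.98e6, seed=0))
fit = double_log_fit(extract_quench_curve(series), series.protein_conc)
print(f"Ka = {fit.K_a:.3g} /M, n = {fit.n_sites:.3f}, R^2 = {fit.R_squared:.4f}")

# thermodynamics from per-temperature binding constants
thermo = vant_hoff_fit({298: 3.98e6, 303: 8.13e6, 308: 13.99e6})
print(f"dH = {thermo.delta_H/1e3:.2f} kJ/mol, dS = {thermo.delta_S:.2f} J/(mol K), "
      f"force: {thermo.force_interpretation}")

rec = docking_postprocess(-8.17, 298.0)
print(f"docking: {rec.delta_G_kcal} kcal/mol -> {rec.delta_G_kJ:.2f} kJ/mol, "
      f"K_i = {rec.K_i:.3g} M")
```

prints

```
Ka = 3.98e+06 /M, n = 1.000, R^2 = 1.0000
dH = 95.99 kJ/mol, dS = 448.66 J/(mol K), force: hydrophobic
docking: -8.17 kcal/mol -> -34.18 kJ/mol, K_i = 1.02e-06 M
```

The recovered Ka and unit slope confirm the double-log estimator is exact on
ideal 1:1 data; the positive ΔH⁰ and ΔS⁰ mark an entropy-driven, hydrophobic
association whose ΔG⁰ (−37.71 kJ/mol at 298 K, from ΔH⁰ − TΔS⁰) is
spontaneous; the docking energy maps to a micromolar inhibition constant.

A full study — several temperatures, optional marker and synchronous series,
docking energies — runs from one YAML config:

```
quenchbind run --config study.yaml --out report.json
```

with subcommands `simulate`, `quench`, `bind`, `displace`, `thermo`,
`syncshift` and `dock-post` for the individual stages.

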