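# Methods

## Physical model

A protein with a single dominant fluorophore (serum albumin's tryptophan,
emission maximum near 337 nm) is titrated with a ligand at fixed protein
concentration. Two quenching mechanisms are modelled:

* **Static**: the ligand forms a ground-state 1:1 complex that is dark (or
  dim). The observed intensity is proportional to free protein plus
  `complex_brightness` times the complex. The equilibrium
  P + Q ⇌ PQ with constant K_a is solved exactly: [PQ] is the root of
  K_a·x² − (K_a([P]+[Q])+1)·x + K_a[P][Q] = 0 in [0, min([P],[Q])],
  evaluated as x = 2c/(b + √(b²−4ac)) to avoid cancellation at both small
  and large K_a.
* **Competitive static**: a site marker M shares the pocket,
  P + Q ⇌ PQ and P + M ⇌ PM. Free protein p solves
  p·(1 + K_Q[Q]/(1+K_Q p) + K_M[M]/(1+K_M p)) = [P]; the left side is
  strictly increasing in p, so bracketed Brent root-finding on [0, [P]] is
  globally convergent (tolerance near machine epsilon; mass balances hold to
  ~1e−12 relative).
* **Dynamic**: purely collisional, F = F₀/(1 + K_SV[Q]) with no ground-state
  association.

## Estimators

**Inner-filter correction.** F_cor = F_obs·10^((A_ex+A_em)/2), element-wise.
Applied only when both absorbances were recorded; negative absorbances are
rejected as corrupt input.

**Curve extraction.** Peaks are located by 3-point parabolic interpolation
around the discrete argmax (sub-grid shifts of 1–2 nm on ~1 nm grids are
meaningful; interpolation error on Gaussian bands is < 0.2 nm). F is read at
the zero-quencher spectrum's peak wavelength, held fixed across the series,
so all F₀/F ratios compare one wavelength. A fixed-wavelength mode overrides
this.

**Stern–Volmer.** OLS of F₀/F on [Q]; the slope is K_SV, the intercept is
fitted freely (not pinned to 1) and reported, R² is the squared Pearson
correlation. K_q = K_SV/τ₀ with τ₀ = 1.0×10⁻⁸ s by default — the value
consistent with published K_q/K_SV ratios for albumin; τ₀ is a parameter
because the literature also quotes 8 ns. The mechanism call uses *strict*
monotonicity of K_SV across temperatures plus the diffusion-limit test
K_q ≷ 2×10¹⁰ M⁻¹s⁻¹; the two lines of evidence must agree, otherwise the
verdict is `indeterminate` with both flags reported. Ties count as
non-monotone — a reproducible rule in preference to within-error judgement.

**Double-log binding fit.** y = log₁₀((F₀−F)/F) against
x = log₁₀([Q] − [P](F₀−F)/F₀), base-10 throughout. Total ligand is used as
the starting [Q] (the equilibrium concentration is unmeasurable) with the
[P](F₀−F)/F₀ term as the depletion correction. Points with non-positive log
arguments are dropped and counted — the log is undefined there and any
imputation would alter the model. For a dark 1:1 complex the plot is exactly
linear with slope 1 and intercept log₁₀K_a (since (F₀−F)/F = [PQ]/[P_free]
and the corrected argument equals free ligand), which is the analytic oracle
used in the tests: noise-free recovery is exact to ~1e−13 relative.

**Van't Hoff.** OLS of ln K_a on 1/T; ΔH⁰ = −R·slope, ΔS⁰ = R·intercept,
R = 8.314 J/(mol·K). ΔG⁰(T) defaults to ΔH⁰ − TΔS⁰ (self-consistent with
the fitted pair and the convention behind published tables); the direct
−RT·ln K_a route is exposed separately and agrees within the fit residual
(≤ 0.2 kJ/mol on the reference data). Force interpretation: ΔH⁰>0, ΔS⁰>0 →
hydrophobic; ΔH⁰<0, ΔS⁰<0 → van der Waals/H-bond; |ΔH⁰| < 4 kJ/mol with
ΔS⁰>0 → electrostatic (the "≈ 0" band needs an explicit width; 4 kJ/mol,
configurable, makes the rule total — the electrostatic band takes precedence
inside it); anything else → `other`.

**Displacement.** Percent reduction 100·(K_a,binary − K_a,ternary)/K_a,binary
per marker; the strictly larger reduction calls the site. A K_a increase
under both markers yields `indeterminate` with a warning (negative
displacement indicates a fit or labelling problem, not competition). The
operation is temperature-agnostic beyond requiring all three fits at one
temperature.

**Synchronous shifts.** Net shift = interpolated peak at the highest
concentration minus at zero; |shift| ≤ 0.5 nm (configurable) is `none` —
published work calls 2 nm a "small" shift and 0 nm no change, so the default
sits well below the smallest shift treated as real. Δλ = 15/60 nm series are
labelled Tyr/Trp probes; no structural inference is computed from the labels.

**Docking post-processing.** kJ = 4.184·kcal (thermochemical calorie);
K_i = exp(ΔG/RT), a concentration in mol/L (an equilibrium dissociation
scale; positive ΔG is allowed and gives K_i > 1 M).

## Synthetic data: what it does and does not emulate

Defaults mirror a standard albumin titration: [P] = 1.6×10⁻⁶ M, [Q] = 0 to
3.2×10⁻⁶ M in 9 steps, emission scanned 300–450 nm on a 1 nm grid, Gaussian
band at 337 nm (σ = 25 nm), excitation 295 nm, dark complex
(`complex_brightness` = 0). Multi-temperature series derive K_a(T) from a
chosen (ΔH⁰, ΔS⁰) via the van't Hoff relation. Noise is multiplicative
Gaussian on each intensity sample (default off; 1% in the calibration
study), with optional additive baseline noise; the generator is
`numpy.random.default_rng` (PCG64), seeded, and the seed is recorded in the
truth record — identical configs are bit-identical.

Not emulated: scattering and Raman bands, photobleaching, instrument
baseline drift, wavelength-correlated (pink) noise, inner-filter attenuation
(absorbance columns can be attached but spectra are not attenuated), and any
n ≠ 1 stoichiometry. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to every artefact of real
instruments; in particular real spectra have smooth, correlated noise where
the generator's is white.

## Calibration caveat: double-log error bars under strong depletion

A 500-replicate study at the default conditions (K_a = 3.98×10⁶ M⁻¹,
1% multiplicative noise) shows the fitted log₁₀K_a falling within 3 reported
standard errors of truth in only ~34% of replicates, far below nominal. The
cause is structural, not a bug: when binding is strong, free ligand
[Q] − [P](F₀−F)/F₀ is a small difference of comparable numbers, so the
*abscissa* of the regression is noisy at the low-concentration points, which
also carry the highest leverage. OLS attributes those x-errors to the slope
rather than the residuals, and the intercept — extrapolated ~6 log-units
outside the data — inherits an underestimated standard error and a downward
bias (errors-in-variables attenuation; reading the peak of a noisy spectrum
adds a further ~2% selection bias to F₀). Noise-free recovery is exact, and
calibration recovers only in weak-depletion regimes (K_a·[P] ≪ 1). Users
should treat double-log standard errors as optimistic whenever the depletion
correction is a sizeable fraction of [Q]; replicate titrations remain the
honest error estimate.

## Problem sizes and numerics

All fits are closed-form OLS (scipy's linregress); equilibrium solves are a
quadratic or a bracketed Brent iteration, microseconds each. The test suite
(117 tests, including hypothesis property sweeps and the 500-replicate
calibration study) runs in a few seconds on one core; the acceptance script
likewise. Rounding happens only at presentation (2 decimals for kJ/mol, 2–3
significant figures for constants); reports retain full precision in JSON.
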