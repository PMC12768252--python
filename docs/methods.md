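# Methods

This note records the model, the estimators, the synthetic-data generator
and the numerical/design choices behind `guvkinetics`, in the spirit of a
package methods appendix. Nothing here states a result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Electromechanics

The forward map from applied field to membrane tension assumes a spherical
vesicle that behaves as a thin, poorly conducting dielectric shell in
conductive aqueous media, in the low-frequency (quasi-static) limit. Under
those assumptions the induced transmembrane voltage is V_m = 1.5 R E |cos θ|
(Schwan), maximal at the poles; all downstream computations use the pole
value θ = 0, because rupture is governed by the most-stressed part of the
membrane. The capacitive (Maxwell-stress) tension is
σ_e = ε_m ε_0 (h/2h_e²) V_m².

Defaults, SI units internally:

| parameter | default | meaning |
|---|---|---|
| ε_m | 4.5 | relative membrane permittivity |
| ε_0 | 8.85e-12 F/m | vacuum permittivity (see below) |
| h | 4e-9 m | membrane thickness |
| h_e | 2.8e-9 m | membrane dielectric thickness |
| T | 298.15 K | assay temperature (25 °C) |
| B | 1.76e-3 N/m | electrostatic tension from surface charge |

ε_0 is deliberately the three-significant-figure value: it makes the
composite pole-tension coefficient 2.25 ε_m ε_0 h/(2h_e²) round to exactly
22.86 mN m⁻¹ m⁻² (V/m)⁻², the conventional coefficient for this membrane
system; the CODATA value yields 22.87 and can be substituted through
`MembraneConstants`. The pulse waveform of the driving signal (kHz pulsed
DC) is carried as metadata only — under the quasi-static assumption the
duty cycle does not change σ_e. Out of scope by design: AC/impedance
corrections, conductivity-ratio terms, and field-induced vesicle
deformation.

`field_for_target_tension` inverts the map in closed form; it mirrors the
experimental protocol in which each vesicle's radius is measured first and
the field chosen so that every vesicle experiences the same target tension.

## Pore energetics

The prepore free energy U(r) = 2πrΓ − π(σ_e + B)r² treats the rim cost as
linear in radius (edge tension Γ, a few pN) and the tension gain as
quadratic. Its maximum U_b = πΓ²/(σ_e + B) at r_c = Γ/(σ_e + B) is the
nucleation barrier, and rupture is modelled as thermally activated barrier
crossing: k_r = A exp(−U_b/k_BT). The frequency factor A is treated as a
nuisance parameter — it is fitted (per peptide content) from the intercept
of the linearized rate law, never assumed. Barriers are reported in both J
and k_BT; Γ is held in newtons internally and converted to pN only at the
I/O boundary.

The biphasic model Γ(φ) = Γ₀ + aφ − bφ² describes how a channel-forming
peptide modulates the edge tension with mole fraction φ ∈ [0, 1]. The signs
of a and b are deliberately unconstrained: plausible mechanisms exist for
both initial stiffening and initial softening, so the implementation
reports the signs the data produce rather than enforcing a narrative. The
CLI accepts mole percent and converts to mole fraction (logged), since
laboratory records usually carry percent. The Helfrich bending-energy
density ½κ(C − C₀)² is provided for curvature-energy estimates around
toroidal-pore formation; pore-shape modelling itself is out of scope, as
are first-passage dynamics on U(r) and peptide dimerization kinetics.

## Survival kinetics

One vesicle yields one record: a rupture time within the observation
window, or a censoring flag (intact at window end). The window is 60 s and
times are recorded on a 1 s frame grid, matching the time-lapse acquisition
the package is designed for. The empirical intact fraction counts censored
vesicles as intact through the whole window; by construction it is
non-increasing, starts at 1 and ends at 1 − d/n.

Two rate estimators are provided:

* `fit_rate_ls` (default): nonlinear least squares of exp(−kt) against the
  empirical curve, with R² — the conventional estimator for this assay, and
  the default because it is what practitioners report. With ceil-to-frame
  quantization the empirical curve evaluated at whole seconds is *exactly*
  unbiased for exp(−kt) (ceil(T) > t ⇔ T > t at integer t), so this
  estimator is insensitive to the 1 s frame resolution.
* `fit_rate_mle`: the censored-exponential maximum likelihood, closed form
  k̂ = d/Σ(exposures), se = k̂/√d. It handles censoring exactly and needs no
  grid, but on frame-quantized times it inherits a half-frame bias
  (k̂ → 1/(1/k + ½) as n → ∞, ≈ −11% at k = 0.25 s⁻¹); it is the better
  choice for continuous times or when censoring dominates.

Aggregation across independent trials defaults to the mean of per-trial
fits with the between-trial standard error, matching how replicate
experiments are usually summarized; a pooled fit is available. Kaplan–Meier
corrections, competing risks and non-exponential survival models are out of
scope; a constant hazard from field onset is assumed throughout.

## Edge-tension inference

ln k_r is regressed on 1/(σ_e + B) by unweighted OLS (default — the
conventional analysis specifies no weighting; inverse-variance weighting by
(k_r_se/k_r)² is available). Γ = √(−slope·k_BT/π); a non-negative slope is
rejected as non-physical. B is passed explicitly so the sensitivity of Γ to
the assumed electrostatic tension can be scanned. A is fitted per peptide
content, not shared.

Uncertainty: the reported Γ_se is the delta-method value
|k_BT/(2πΓ)|·slope_se. The confidence interval, however, is built by
transforming the slope's exact Student-t interval (n−2 dof) through the
monotone map slope → Γ, which avoids the delta linearization at small point
counts. In simulation at the design sizes below, the 95% interval covers
the generating Γ in ≈93–94% of replicates — slightly under nominal, which
is inherent to 5-point regressions with estimated standard errors; the
vesicle-level bootstrap (`bootstrap_gamma`, resampling within tension
groups, since vesicles are the independent replicates) agrees with the
delta SE when both are averaged over replicate designs.

The quadratic Γ(φ) fit runs on the mole-fraction scale without transform,
with optional inverse-variance weights; three distinct φ values determine
it exactly.

## Synthetic data

The generator reproduces the statistical structure of the assay:

* vesicle diameters uniform on 28–32 μm (the protocol's selection band);
* per-vesicle field chosen from the measured radius so each vesicle sits at
  the target tension (optional lognormal tension jitter models
  radius-measurement error, default off);
* latent rupture times exponential with the Arrhenius rate from the
  generating parameters (fixed Γ, a Γ-per-content table, or the biphasic
  law);
* censoring applied on the *latent* time at the 60 s window — a rupture at
  60.4 s is never observed, which is how a real 60 s watch ends — then
  ceil-quantization to the 1 s frame grid;
* trials of 12–18 vesicles and 2–4 trials per condition, drawn uniformly
  from those ranges unless fixed, to exercise the aggregation code;
* hierarchical seeding (one stream per condition × trial, spawned from the
  single global seed) so adding a condition leaves existing cells
  byte-identical.

What it does **not** emulate: image formation and fluorescence-based
rupture detection (rupture times are generated directly), pre-rupture
leakage, within-pulse rate modulation, or any deviation from constant
hazard. Passing tests therefore validate the statistical pipeline under
the model's own assumptions, not the microscopy or the constant-hazard
assumption itself.

## Problem sizes and numerics

The end-to-end recovery study (tests and acceptance script) uses the
assay's own design sizes: 15 vesicles × 3 trials per tension, five target
tensions at 1.5–2.8 mN/m chosen with the generating parameters (Γ = 6 pN,
A = 100 s⁻¹) so the rates span ≈0.02–0.24 s⁻¹ — the window actually
observable with a 60 s watch at 1 s/frame, and the same decade as measured
rate constants in this assay class — repeated over 200 seeded replicates.

Numerical choices: exponential curve fits use bounded least squares with
tight (1e-12) tolerances and a moment-based start; the exactly-determined
3-point quadratic fit has undefined coefficient SEs (reported as NaN);
zero total tension raises rather than returning infinities; rates of
exactly zero simulate as always-censored vesicles. All randomness flows
from numpy `SeedSequence`; no global RNG state is touched.

## Known limitations

* The MLE's half-frame quantization bias is documented but not corrected;
  an interval-censored (geometric) variant would remove it and is a natural
  extension.
* CI coverage for Γ is ≈1–2 points under nominal at 5-tension designs (see
  above); users needing exact coverage should increase the number of
  tensions or use the bootstrap.
* The radius plausibility warning (10–20 μm) reflects the selection band of
  the protocol this package models; other assays may legitimately differ.
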