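# guvkinetics

Rupture kinetics of giant unilamellar vesicles (GUVs) under applied electric
fields: from field and vesicle geometry to induced membrane tension, from
censored per-vesicle rupture times to survival curves and rate constants, and
from rate constants at multiple tensions to the pore-edge (line) tension of
the membrane — including its biphasic dependence on the content of a
channel-forming peptide (gramicidin A).

The package is aimed at membrane biophysicists running single-vesicle
electroporation assays: it provides the forward physics, the statistical
estimators for the resulting (right-censored, frame-quantized) rupture-time
data, and a synthetic-data generator that emulates the assay so every stage
of the analysis can be validated offline.

## The model

A spherical vesicle of radius *R* in a uniform quasi-static field *E*
develops a transmembrane voltage (Schwan equation)

    V_m = 1.5 R E |cos θ|,

maximal at the poles. The stored capacitive energy appears as an in-plane
electric tension

    σ_e = ε_m ε_0 (h / 2h_e²) V_m²  ≈  22.86 R²E²  mN/m

with membrane permittivity ε_m ≈ 4.5, thickness h ≈ 4 nm and dielectric
thickness h_e ≈ 2.8 nm. A transient pore of radius *r* in the tensed
membrane has free energy

    U(r) = 2πrΓ − π(σ_e + B) r²,

where Γ is the pore-edge tension and B an electrostatic tension from the
membrane surface charge (1.76 mN/m for the charged DOPG/DOPC membranes this
package was built around). The barrier U_b = πΓ²/(σ_e + B) at the critical
radius r_c = Γ/(σ_e + B) sets an Arrhenius rupture rate

    k_r = A exp[−πΓ² / ((σ_e + B) k_B T)],

so the fraction of intact vesicles decays as P_intact(t) = exp(−k_r t), and
a straight-line fit of ln k_r against 1/(σ_e + B) over several tensions
yields Γ from the slope and the frequency factor A from the intercept.
Across peptide mole fraction φ the edge tension follows the quadratic
(biphasic) model Γ(φ) = Γ₀ + aφ − bφ².

## Worked example

```sh
$ guvkinetics tension --radius-um 10 --field-v-per-cm 553
V_m = 0.8295 V
sigma_e = 6.99 mN/m
```

A 10 μm vesicle in a 553 V/cm field develops 0.83 V across its poles and an
induced lateral tension of ~7 mN/m — enough to porate on a seconds
timescale.

```sh
$ guvkinetics energetics --gamma-pn 9.6 --sigma-mn-per-m 8 --a-per-s 300
r_c = 0.9836 nm
U_b = 2.966e-20 J = 7.207 kBT
k_r = 0.2225 1/s
```

At 8 mN/m, a membrane with Γ = 9.6 pN has a ~1 nm critical pore radius and
a ~7 k_BT nucleation barrier, giving a rupture rate of 0.22 s⁻¹: the median
vesicle ruptures within a few seconds of field onset.

Simulate a five-tension study at that edge tension and re-infer it:

```sh
$ guvkinetics simulate --gra 0 --gamma-pn 9.6 --a-per-s 300 \
    --sigma-mn-per-m 5 --sigma-mn-per-m 6 --sigma-mn-per-m 7 \
    --sigma-mn-per-m 8 --sigma-mn-per-m 10 \
    --n-vesicles 15 --n-trials 3 --seed 42 --out demo.csv
$ guvkinetics report demo.csv
guvkinetics 0.1.0  seed=0  config=029dd65fe333

  GrA%  sigma(mN/m)    n   k_r(1/s)       se  P_rup
     0            5   45    0.01503   0.0019  0.578
     0            6   45     0.0359   0.0054  0.844
     0            7   45    0.08371    0.013  0.978
     0            8   45      0.243     0.03  1.000
     0           10   45     0.7342    0.058  1.000

  GrA%  Gamma(pN)     se     A(1/s)     R2
     0      9.098   0.31      142.9  0.986
```

The rate constant climbs steeply with tension (0.015 → 0.73 s⁻¹ across
5–10 mN/m), and the linearized fit recovers the generating edge tension
(9.1 ± 0.3 pN against a truth of 9.6 pN, 45 vesicles per tension) together
with an estimate of the frequency factor.

The same pipeline is available as a library: `tension_from_field`,
`rupture_rate`, `empirical_survival`, `fit_rate_ls` / `fit_rate_mle`,
`fit_edge_tension`, `fit_biphasic`, and `ExperimentDesign` /
`simulate_tension_grid` for synthetic data. See `docs/methods.md` for the
estimators, their assumptions, and the generator's fidelity and limits.

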