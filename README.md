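# bzfit

Thermodynamic modelling and fitting of the protein-induced B-Z transition
of short DNA duplexes, as observed by NMR titrations.

Z-DNA-binding proteins (ZBPs — the Zα domains of ADAR1, DAI, E3L, PKZ)
convert d(CG)-repeat duplexes from the right-handed B form to the
left-handed Z form through a sequential four-state mechanism:

```
B + P ⇌ BP          dissociation constant  K_d,BP      (μM)
BP    ⇌ ZP          conformational step    K_BZ,1 = [ZP]/[BP]
ZP + P ⇌ ZP₂        dissociation constant  K_d,ZP2     (μM)
```

One protein first binds B-DNA (BP), shifts the conformational equilibrium
to the Z form (ZP), and a second protein then locks the Z helix (ZP₂).
Given total concentrations [P]ₜ and [N]ₜ, mass balance reduces to a monic
cubic in the free protein [P],

```
[P]³ + a[P]² + b[P] + c = 0
a = 2[N]ₜ − [P]ₜ + (1 + 1/K_BZ,1)·K_d,ZP2
b = (1 + 1/K_BZ,1)·K_d,ZP2·([N]ₜ − [P]ₜ) + K_d,BP·K_d,ZP2/K_BZ,1
c = −K_d,BP·K_d,ZP2·[P]ₜ/K_BZ,1
```

which `bzfit` solves analytically (trigonometric/hyperbolic branches with
a bracketing fallback) and turns into the three NMR observables:

* **imino-proton hydrogen-exchange rates** `k_ex` of the DNA, as closed
  curves in the molar ratio χ = [P]ₜ/[N]ₜ (half-stoichiometry regime,
  K_BZ,1 = 1) or in the Z fraction f_Z = Zₜ/[N]ₜ, for probes on the
  Z-form (`kex_ZP → kex_ZP2`) or residual B-form (`kex_B → kex_BP`)
  resonances;
* **amide chemical-shift perturbations** of the protein,
  Δδ_obs = ([BP]/[P]ₜ)·Δδ_B + (([ZP]+2[ZP₂])/[P]ₜ)·Δδ_Z;
* **Z-DNA fractions** f_Z in either the DNA- or protein-normalized
  convention.

Fitting these observables recovers the equilibrium constants: the
exchange-curve fits give the shape constants (α, K_BZ,1), and the global
multi-probe shift + f_Z fit gives the absolute constants
(K_d,BP, K_d,ZP2, K_BZ,1). Everything is testable without external data
through a seeded synthetic-titration generator.

The estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling; `lmfit` drives the weighted least squares with
deterministic Latin-hypercube multi-start and log₁₀ parameterization of
all positive constants.

## Worked example

Solve the species partition at the tight-binding constants of the PKZ Zα
domain at low salt (K_d,BP = 0.028 μM, K_d,ZP2 = 0.345 μM, K_BZ,1 = 0.87)
for a 50 μM duplex half-saturated with protein:

```python
from bzfit import ModelParams, MixtureComposition, solve_species

params = ModelParams(Kd_BP=0.028, Kd_ZP2=0.345, K_BZ1=0.87)
state = solve_species(params, MixtureComposition(P_total=25.0, N_total=50.0))
print(f"free protein [P] = {state.P_free:.4f} uM")
print(f"[B] = {state.B:.3f}  [BP] = {state.BP:.3f}  [ZP] = {state.ZP:.3f}  [ZP2] = {state.ZP2:.3f} uM")
print(f"f_Z = {state.f_Z_dna:.3f}")
```

```
free protein [P] = 0.0141 uM
[B] = 25.473  [BP] = 12.870  [ZP] = 11.197  [ZP2] = 0.459 uM
f_Z = 0.233
```

Nearly all protein is bound (14 nM free out of 25 μM), split almost
evenly between BP and ZP as K_BZ,1 ≈ 0.9 dictates; only 23% of the DNA is
Z-form because the second, weaker binding event (K_d,ZP2 ≈ 12·K_d,BP) has
barely engaged at χ = 0.5.

Simulate a noisy multi-probe titration at those constants (8 amide
probes, 12 compositions spanning [N]ₜ = 0.5–50 μM, σ_shift = 0.005 ppm,
σ_fZ = 0.02) and fit it back globally:

```python
from bzfit import fit_global_shifts
from bzfit.synthetic import spec_for_reference_system, simulate_dataset
from bzfit.reference import BINDING_SYSTEMS

spec = spec_for_reference_system(BINDING_SYSTEMS[0], noise_scale=1.0, seed=7)
result = fit_global_shifts([simulate_dataset(spec)])
print(result.summary())
```

```
converged: True   objective: 71.6523   n_points: 108
  kd_bp = 0.0279413 +/- 0.000679
  kd_zp2 = 0.332076 +/- 0.00748
  k_bz1 = 0.800526 +/- 0.0309
```

The generating truth (0.028, 0.345, 0.87) is recovered within a few
percent on the dissociation constants; the conformational constant lands
two standard errors low for this noise realization — typical of its
sensitivity, which is why `bootstrap_uncertainty` and the Monte-Carlo
`recovery_study` are part of the package.

The same workflows are scriptable from the shell:

```sh
bzfit simulate --kind kex_zform --seed 2 --out zform.csv
bzfit fit --data zform.csv --model zform --out report.json
bzfit recover --kind shift_and_fz --n 100 --seed 0 --out recovery/
bzfit fixtures --out fixtures/ --seed 0
```

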