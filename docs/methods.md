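# Methods

## The model

`bzfit` implements the equilibrium thermodynamics of ZBP-induced B-Z DNA
transitions as a four-state sequential mechanism on a DNA duplex N and a
protein P:

    B + P ⇌ BP        Kd_BP   = [B][P]/[BP]        (μM)
    BP    ⇌ ZP        K_BZ1   = [ZP]/[BP]          (dimensionless)
    ZP + P ⇌ ZP₂      Kd_ZP2  = [ZP][P]/[ZP₂]      (μM)

Assumptions: pure equilibrium (no kinetics), one duplex binding at most
two proteins, no direct B → Z conversion of free DNA (free Z-DNA is a
negligible population for a 6-bp duplex), and ideal-dilute mass action.
The BP₂-first mechanism seen for some Zβ domains is out of scope: no
closed equilibrium treatment of it exists to implement.

All concentrations are μM internally; the I/O layer converts nM/mM
columns on input. The derived ratio α = Kd_ZP2/Kd_BP is exposed as a
read-only property of `ModelParams`.

### Species solution

Given totals ([P]ₜ, [N]ₜ), the four DNA species share the denominator
D = Kd_BP·Kd_ZP2 + (1+K_BZ1)·Kd_ZP2·[P] + K_BZ1·[P]², and protein mass
balance closes the system as a monic cubic in the free protein [P].
Because the bound-protein function is strictly increasing in [P], the
physical root in [0, [P]ₜ] is unique.

The analytic solver uses the trigonometric branch
[P] = −a/3 + (2/3)√(a²−3b)·cos(θ/3) when the cubic has three real roots,
evaluating all three candidates (θ+2πk)/3 and requiring exactly one
inside [0, [P]ₜ] (slack 10⁻⁹·max(1, [P]ₜ)); in the one-real-root regime
(a²−3b < 0, or arccos argument outside [−1, 1], which covers roughly a
quarter of the physically admissible parameter space) it switches to the
standard hyperbolic cosh/sinh branches of the same analytic solution.
Two Newton steps on the mass-balance residual polish the root: the
trigonometric form computes the root as a difference of terms of order
|a|, which costs relative precision when the root is many orders of
magnitude smaller (tight binding at high concentrations). Every root is
verified against the cubic (residual < 10⁻⁹ of the largest term). A
bracketing solver (Brent on the mass-balance residual, xtol
10⁻¹²·max(1, [P]ₜ)) serves as independent oracle and as fallback when
rounding makes candidate selection ambiguous; degenerate inputs
([P]ₜ = 0, [N]ₜ = 0) are answered exactly before any root finding.
K_BZ1 = 0 is rejected as a degenerate mechanism (the coefficients divide
by it); fitting paths bound K_BZ1 ≥ 10⁻³.

## Observables

**Exchange-rate curves.** The imino-proton exchange rate observed on a
resonance is the population-weighted average of limiting rates over the
states in fast exchange with it: {ZP, ZP₂} for a Z-form probe
(kex_ZP, kex_ZP2), {B, BP} for a B-form probe (kex_B, kex_BP). Three
closed curves are provided: k_ex(χ) for Z-form probes in the
half-stoichiometry regime (K_BZ1 = 1, tight binding, χ ≤ 2 — outside
that regime the curve is not claimed valid and callers must use the
species-weighted path), and k_ex(f_Z) for Z-form and B-form probes in
general.

*Parameter convention.* The curve parameters (α, K_BZ1) follow the
standard exchange-curve parameterization in which published constants for
these systems are reported. They are the **reciprocals** of the
species-model ratios: for every f_Z, the curves satisfy (to machine
precision)

    curve(α, K_BZ1, f_Z) == population average of the four-state model
                            at Kd_ZP2/Kd_BP = 1/α, [ZP]/[BP] = 1/K_BZ1.

The test suite asserts this identity against an independent oracle that
solves the species-fraction quadratic obtained by eliminating the free
protein. Physically, α → 0 in the curve convention means the second
binding event is much weaker than the first, giving sequential filling
(ZP first, ZP₂ past one equivalent) — the regime the d(CGCGCG)₂ data
show. Published α values for the non-CG duplexes equal the inverse Kd
ratio Kd_BP/Kd_ZP2 of the same rows, consistent with this convention;
`bzfit.reference` records the printed numbers uncorrected and flags the
affected rows (`alpha_matches_inverse_kd_ratio`).

*Numerics.* The printed curve forms carry removable singularities
(χ → 0, f_Z → 0, α → 1). All three are evaluated through an exact
conjugate rearrangement — the brace m − √(m²−q) is rewritten as
q/(m + √(m²−q)), after which the singular prefactor cancels
algebraically — so no series switch or threshold is needed and the
endpoint identities (k_ex = kex_ZP2 exactly at χ = 2 and f_Z = 1) hold
without rounding. Square-root arguments within −10⁻¹² are clamped to
zero; larger violations raise a domain error.

**Chemical-shift perturbations.** Δδ_obs = ([BP]/[P]ₜ)·Δδ_B +
(([ZP]+2[ZP₂])/[P]ₜ)·Δδ_Z, the ZP₂ state counting twice because both of
its proteins are Z-bound. Undefined at [P]ₜ = 0.

**Z fractions.** Both conventions are first-class: f_Z_dna = Zₜ/[N]ₜ
(used for titration curves and the half-stoichiometry relation) and
f_Z_protein = ([ZP]+[ZP₂])/[P]ₜ. The global fit uses the DNA convention
by default, switchable per run.

## Fitting

Weighted least squares with per-point σ when provided (else unit
weights), minimized by `lmfit`'s trust-region least squares. All positive
constants are fitted in log₁₀ space by default (bounds: Kd ∈ [10⁻⁴, 10⁴]
μM, K_BZ1 ∈ [10⁻³, 10²], α ∈ [10⁻⁴, 10³]); a linear-space mode exists
and agrees to < 10⁻⁶ relative on zero-noise data. Limiting rates are
fitted in linear space with data-driven bounds [0, 3·max|y|], or held
fixed when supplied. Each fit runs 8 deterministic Latin-hypercube starts
(seeded; one start is the data-driven initial guess) and keeps the best
optimum.

The global shift + f_Z fit exploits that Δδ_obs is linear in the
per-probe (Δδ_B, Δδ_Z): at every residual evaluation the shifts are
profiled out exactly by weighted linear least squares (variable
projection), so the nonlinear search is three-dimensional regardless of
the number of probes. Reported shift uncertainties are conditional on
the fitted constants; joint uncertainty comes from the bootstrap.

Diagnostics are explicit rather than silent: fewer than 5 points per free
parameter warns and flags `few-points`; a singular covariance flags
`rank-deficient`/`non-identifiable` (e.g. kex_BP = kex_B removes all
signal from a B-form curve); relative 1σ above 10 flags
`weakly-identified`; non-convergence is flagged and the CLI exits
non-zero.

**Bootstrap.** Case-resampling percentile intervals (16/50/84), points
resampled with replacement stratified by probe and observable for global
fits, deterministic under seed, skipped-replicate counts reported. By
default each refit is warm-started from the point estimates (fast and
adequate for well-identified fits). For weakly identified fits the warm
start cannot leave a flat valley and the interval is deceptively narrow —
measured directly when f_Z data are ablated from a global fit — so
`n_starts > 1` switches to cold multi-start refits; the ablation test
uses 4 starts, under which removing the f_Z curves widens the Kd_ZP2
interval by an order of magnitude.

## Synthetic data

The generator computes noise-free observables through the solver and
forward models, then applies: Gaussian noise on shifts (default σ = 0.005
ppm) and f_Z (σ = 0.02, clipped to [0, 1]), and mean-preserving
log-normal multiplicative noise on exchange rates (default CV = 5%;
σ_ln = √ln(1+cv²) with −σ²/2 mean correction, so the sample CV matches
the nominal value exactly). These σ defaults are generator placeholders
— realistic orders of magnitude for NMR-derived quantities, not measured
uncertainties — and the fixture manifest says so. Datasets are
byte-reproducible under a fixed seed and record their generating truth.

Designs: exchange-rate titrations default to 12 χ points from 0.17 to
2.0 at [N]ₜ = 100 μM, a typical NMR titration of a short duplex. The
shift/f_Z design instead crosses [N]ₜ ∈ {0.5, 5, 50} μM with χ ∈ {0.25,
0.75, 1.5, 2.5} (12 compositions, 8 probes: four ¹H-scale and four
¹⁵N-scale shift pairs of mixed sign). The two-dimensional design is
essential: at a single [N]ₜ far above the Kd values the populations
depend only on (α, K_BZ1, χ) and the absolute Kd scale is unidentifiable;
spanning concentrations from sub-μM to tens of μM keeps dissociation
constants from ≈ 0.03 to ≈ 60 μM — the span of the published
condition series — recoverable.

What the generator does **not** emulate: raw spectra, peak picking,
exchange-rate measurement error structure beyond a constant CV,
probe-to-probe σ heterogeneity, baseline/referencing drift, or
aggregation at high protein excess. Passing recovery tests therefore
demonstrate correctness of the solver-fit pipeline under the model's own
assumptions, not robustness to real-data artifacts.

## Parameter-recovery studies

`recovery_study` simulates seeded replicates at a known truth, fits each,
and `summarize_recovery` reports median relative errors. Problem sizes
used by the shipped studies: 200 replicates for exchange curves, 100 for
the global fit, 12–20 points per curve — small enough to run routinely,
large enough for stable medians.

Identifiability limits found with these studies (and confirmed by
Cramér-Rao analysis) are documented behavior, not defects: from a
ratio-domain exchange curve at 5% noise, α near the extremes of the
published span is weakly determined (at α ≈ 10⁻², no estimator can beat
~60% median relative error with 20 points, because the curve's
α-sensitivity scales as √α near χ = 1); co-fitting the limiting rates
roughly doubles the α error relative to fixing them; and the f_Z-domain
curves lose their information about (α, K_BZ1) as α → 1, where the
discriminant term vanishes. The shipped recovery studies therefore run
at mid-range truths (α = 0.5 ratio-domain, α = 0.3 B-form-domain) with
limiting rates fixed, which measures estimator quality rather than
information-starved designs.

## Known limitations

* Equilibrium only: no time courses, no transition kinetics.
* Two-protein stoichiometry only; no BP₂ intermediate.
* Bootstrap intervals under weak identifiability require cold multi-start
  refits to be honest; the fast warm-started default under-covers there.
* The exchange-curve and species-model parameterizations are reciprocal
  (see above); users mixing constants between the two fitting routes must
  invert the ratios accordingly.
* Published constants bundled in `bzfit.reference` are fixture truths for
  recovery testing; the original titration datasets are not public, so
  those values are not re-derived here.
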