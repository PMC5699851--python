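# Methods

## Scope and assumptions

The package models a homobivalent ligand (or a pair of reversibly
dimerizing monomers) binding a rigid target with two equivalent,
independent sites. The core assumptions, shared by all models here:

- The tether/connector is fully flexible, does not interact with the target,
  and does not perturb the intrinsic monomer–site affinity K_D.
- The two target sites are equivalent and independent; occupancy of one does
  not change the affinity of the other (tandem-domain proteins and
  homo-oligomeric receptors approximate this well; allosteric or asymmetric
  two-site targets are out of scope).
- Only 1:1, 1:2, 2:1-type complexes on a single target are tracked via
  reacted-site probabilities; higher-order chains and aggregates are not
  modeled.
- Concentrations are molar activities; no non-ideality corrections.

## Effective concentration of a tethered partner

When one ligand of a pair is bound, its free partner samples a sphere of
radius ρ_p (the fully extended ligand–ligand separation). One molecule in
that sphere is

    C(ρ_p) = k / ρ_p³,  k = 3·10²⁷ / (4π N_A) = 396.4245 M·Å³.

The prefactor is computed from the CODATA Avogadro constant at import time
rather than hard-coded; it rounds to 396.4 at four significant figures, and
the derived constants follow: the paired-moiety prefactor 8k (= 3171.396;
the commonly quoted 3171.2 is 8 × the pre-rounded 396.4) and the bulk
crossover prefactor k^{1/3} = 7.346. The tests pin these roundings so a
transcription error in the constant would be caught.

Bridging requires ρ_p ≥ ρ_s (the inter-site distance); the boundary
ρ_p = ρ_s is treated as spanning. For reversible dimers, each monomer
contributes a connector of ρ_p/2, so each linker moiety samples a
half-radius sphere: L_eff = 8k/ρ_p³. When ρ_p greatly exceeds ρ_s the two
moiety spheres overlap almost completely and the true effective
concentration approaches twice this value; the package applies the
half-radius form uniformly (no interpolating factor between the limits),
which keeps the model a single closed form and biases reversible-dimer
folds conservatively at long tethers. This is one reason the ~4-fold
tether-length thresholds below carry a generous tolerance.

The uniform rigid-sphere picture is deliberately simple: no worm-like-chain
or Gaussian-coil end-to-end distributions, no excluded volume, no
rotational restriction. At very short tethers (≲ 5–10 Å) the model
overestimates sphere sampling and hence fold improvements.

## Irreversible bivalent on a two-site target

With F ≡ F_T,Dim the bridged fraction (single-site mass action at
L₀ = T₀ = L_eff), the target population splits into unbound, singly bound,
doubly-separately bound, and bridged 1:1 states. The identities

    F_21 = R F / (1 − R (1 − F)),  F_T = R (1 − F),
    F_2u = (1−F_T)²(1−F_21),  F_1u = 2F_T(1−F_T)(1−F_21),  F_22 = F_T²(1−F_21)

are enforced to 1e-12 in tests. At R = ½ the governing relation is linear
in L₀, so the EC50 closed form

    EC50 = K_D (1 − F) / (2 (1 + F)) + T₀/2

is exact at any target concentration — no root-finding is needed for the
EC50 itself (the general occupancy curve R(L₀) does use bracketed Brent
root-finding on the monotone residual, and the model saturates at R = 1 at
a finite L₀, an artifact of keeping F independent of R).

Derived screening quantities:

- **K₂** (closed 1:1 complex): K₂ = K_D (1 − F²)/(4F), asymptotically
  √(K_D³/4L_eff); its log-log slope versus K_D is 1.5 ± 0.01 over
  K_D ∈ [1e-9, 1e-5] at fixed tether — the 3/2-power rule.
- **Best attainable dimer affinity**: K_D^{3/2} on the molar scale
  (equivalently dimer ΔG = 1.5 × monomer ΔG). The molar standard state is a
  dimensional convention, not derivable; it is adopted because it is the
  scale on which the rule reproduces the known worked examples (600 nM from
  72 µM, ~20 pM from 70 nM, ~0.25 pM from 4 nM).
- **Squared-scaling tether**: K₂ ∝ K_D² would require
  L_eff = 1/(4K_D), i.e. ρ_p = (4kK_D)^{1/3} ≈ 1.2 Å at K_D = 1 mM —
  physically unattainable, which is the point.

## Reversibly dimerizing monomers

The ligand pool splits into monomer fraction F_ML, non-1:1 dimer fraction
F_DL, and the 1:1 fraction D_21, with the solution dimer fraction given in
closed form by 2M ⇌ D mass action at total monomer L₀. The 1:1 target
fraction F_21 is blended between two route limits:

- monomeric route: F_21 = R(1 − R(1−F_L,Dim²)/2 − √(R²(1−F_L,Dim²)²/4 +
  (1−R)(1−F_L,Dim))), with F_L,Dim the on-target linker-pairing fraction;
- dimeric route: the irreversible formula with F_T,Dim evaluated at the
  assembled-dimer span ρ_p (sphere at ρ_p, moieties at ρ_p/2).

Route weights are the relative abundances of doubly-monomer-bound targets
(∝ R F_ML²) and singly-dimer-bound targets (∝ 2(1−R) F_DL), evaluated in
the D_21 = 0 limit so that F_ML = 1 − F_DL; at R = ½ they reduce to
(1−F_DL)²/(1+F_DL²) and 2F_DL/(1+F_DL²). The blend is exact in both pool
limits and interpolates in between; it is an approximation, not a full
equilibrium solution, when K_Dim ≈ L₀.

The EC50 solves L₀ = K_D(1 − 2F_21(L₀)), restricted to R = ½ with T₀ ≪ L₀
(general-R isotherms for this model are not exposed). The production solver
is Brent bracketing on log₁₀L₀ over [K_D·10⁻¹⁴, K_D] at relative tolerance
~1e-15; g(L₀) is positive at the lower end and non-positive at K_D. g is
*not* strictly monotone — shifting route weights produce relative wiggles
of order 1e-5 in mixed regimes — but numerical scans over random parameter
sets find a single sign change, and the independent damped fixed-point
iteration (damping 0.5, started at L₀ = K_D, dimer fraction obtained by
bisection rather than the closed form) agrees with the bracketed root to
1e-8 on randomized parameter sets.

Limiting behavior, all under test: K_Dim → ∞ gives EC50 → K_D (fold 1);
K_Dim → 0 gives exactly twice the irreversible EC50 (the dimer pool is at
half the monomer-equivalent concentration); ρ_p < ρ_s zeroes both routes
(fold 1). The tether-length threshold for a chosen fold target is found by
bisection on ρ_p, using the monotone decrease of fold with tether length;
at K_D = 1 mM the ≥4-fold thresholds are ~18.6 Å for K_Dim = 10 mM and
~42.7 Å for K_Dim = 1 mM (quoted elsewhere as "<16 Å" / "<~40 Å"; the gap
reflects the sphere-overlap approximation above).

## Numerical choices

- Single-site occupancy uses the citardauq form of the quadratic (divide by
  the root-sum, not subtract), which keeps full precision when T₀/L₀ is
  tiny — the common assay regime.
- The pairing closed forms are evaluated as 1 − c/(√(1+x)+1), avoiding the
  subtractive cancellation of the printed forms at small x.
- Validation is strict: negative concentrations/lengths, NaN, and
  non-finite free energies raise typed errors; nothing is clamped silently.
- Test oracles use only 200-step bisection and damped fixed-point iteration,
  sharing no code with production solvers.
- Temperature defaults to 298.15 K for ΔG ↔ K_D conversions
  (R = 1.98720425e-3 kcal/(mol·K)); the worked free-energy examples assume
  ambient temperature.

## Synthetic titration curves

`titration.simulate_titration` generates occupancy curves R(L₀) from the
single-site, two-site-monovalent, or irreversible-bivalent models on a
default grid of 24 points per decade spanning 4 decades centered on the
analytic EC50, with multiplicative lognormal noise (occupancies are
positive and bounded; additive Gaussian noise would not be) clipped to
[0, 1]. The default noise level used in the regression guard is 5 %
relative — typical plate-reader reproducibility. `estimate_ec50` performs
isotonic regression of R on log₁₀L₀ (PAVA, via scipy) and linearly
interpolates the 0.5 crossing. The generator emulates equilibrium binding
with multiplicative read noise only: no baseline/top drift, no depletion or
hook artifacts, no plate effects, so passing recovery tests demonstrate the
estimator's correctness on the model's own terms, not robustness to real
assay pathology.

The suite's problem sizes (grids of a few hundred to a few thousand root
solves, 200-seed regression guards) keep a full run around two seconds
while exercising every closed form against its brute-force oracle.

## Known limitations

- Hetero-dimers (distinct K_Ds), targets with >2 sites, and ligands with
  >2 arms are not modeled.
- The blended-route F_21 is heuristic between the pool limits; expect the
  largest model error when L₀ ≈ K_Dim and both routes contribute.
- No pharmacokinetics, membrane permeation, or dimerization-inhibitor
  effects; predictions are cell-free equilibrium ceilings.
- Tether–protein interactions violate the non-interacting-tether assumption
  and show up experimentally as deviations from the 3/2-rule ceiling in
  either direction.
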