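# avidity

Equilibrium models for predicting how much potency a ligand gains when it is
dimerized — either **irreversibly** (two ligands joined by a flexible tether
into one bivalent molecule) or **reversibly** (monomers carrying linker
moieties that associate in solution with dissociation constant K_Dim) —
against a target with two equivalent, independent binding sites.

The package is aimed at medicinal chemists and assay scientists planning
bivalent / self-assembling-dimer campaigns: given three experimentally
accessible numbers — the monomer dissociation constant K_D, the fully
extended ligand–ligand separation ρ_p (Å), and the target inter-site
distance ρ_s (Å), plus K_Dim for the reversible case — it predicts the EC50
and the fold improvement over the monomer, and provides quick screening
rules for the best attainable dimer affinity.

## Model

Occupancy is described by reacted-site probabilities. When one ligand of a
tethered pair is bound, its partner is confined to a sphere of radius ρ_p,
giving a molar effective concentration

    L_eff = k / ρ_p³,   k = 3·10²⁷ / (4π N_A) ≈ 396.4 M·Å³   (ρ_p ≥ ρ_s, else 0)

The probability that a singly bound pair closes into the bridged 1:1
complex is single-site mass action in that microcosm,

    F_T,Dim = 1 − (K_D / 2 L_eff) [√(1 + 4 L_eff / K_D) − 1],

and the bivalent EC50 at half occupancy (R = ½) is

    EC50_bb = K_D (1 − F_T,Dim) / [2 (1 + F_T,Dim)] + T₀/2,

i.e. a fold improvement of 2 (1 + F)/(1 − F) over the monomeric single-site
reference K_D + T₀/2. In the well-tethered regime (L_eff ≫ K_D) the
effective 1:1 dissociation constant obeys K₂ ≈ √(K_D³ / 4 L_eff) — the
**3/2-power rule**: dimer ΔG ≈ 1.5 × monomer ΔG.

For reversibly dimerizing monomers the 1:1 state forms either from a
pre-formed solution dimer (weight ∝ dimer abundance, bridging probability
F_T,Dim) or by on-target dimerization of two bound monomers (probability
F_L,Dim from the linker effective concentration 8k/ρ_p³ and K_Dim). The EC50
is the self-consistent root of L₀ = K_D (1 − 2 F₂₁(L₀)), solved by bracketed
root-finding; an independent damped fixed-point iteration serves as a
cross-check in the test suite.

## Worked example

```pycon
>>> from avidity import TetherGeometry, ec50_irreversible, ec50_reversible
>>> res = ec50_irreversible(kd=1e-6, geom=TetherGeometry(rho_p=30, rho_s=10))
>>> round(res.f_t_dim, 4), f"{res.ec50_model:.3e}", round(res.fold, 1)
(0.9918, '2.063e-09', 484.7)
```

A 1 µM monomer on a 30 Å tether bridges 99.2 % of singly bound complexes,
pushing the EC50 to ~2 nM — a 485-fold gain. The same monomer made
self-assembling (K_D = 1 mM fragment, K_Dim = 10 mM, 16 Å span):

```pycon
>>> r = ec50_reversible(kd=1e-3, kdim=1e-2, geom=TetherGeometry(16))
>>> f"{r.ec50:.3e}", round(r.fold, 2), round(r.f_ml_at_ec50, 3)
('2.219e-04', 4.51, 0.959)
```

Even with >95 % of the ligand pool monomeric, target-templated dimerization
yields a 4.5-fold potency gain — detectable in a screen.

The same calculations are available from the shell:

```bash
avidity irrev --kd 1uM --rho-p 30 --rho-s 10
avidity rev --kd 1mM --kdim 10mM --rho-p 16 --format json
avidity examples          # literature screening-rule table
avidity grid --preset fig2 --out fig2.csv
```

and as narrative scripts under `examples/`.

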