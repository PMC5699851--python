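"""Fold improvement of an irreversibly linked bivalent vs tether length.

A 1 µM monomer is dimerized with tethers of increasing fully extended
length; the target's two sites are 10 Å apart.  Prints the effective
concentration seen by the second ligand, the bridged fraction, and the
EC50 fold improvement over the monomer.
"""

from avidity import TetherGeometry, ec50_irreversible, gated_effective_concentration

KD = 1e-6  # monomer dissociation constant, M
RHO_S = 10.0  # inter-site distance, Å

print(f"monomer K_D = {KD:.0e} M, site separation = {RHO_S:.0f} A")
print(f"{'rho_p (A)':>10} {'L_eff (M)':>12} {'F_T,Dim':>10} {'EC50 (M)':>12} {'fold':>10}")
for rho_p in (8.0, 10.0, 15.0, 30.0, 60.0, 125.0):
    geom = TetherGeometry(rho_p, RHO_S)
    res = ec50_irreversible(KD, geom)
    L_eff = gated_effective_concentration(geom).value
    print(
        f"{rho_p:>10.0f} {L_eff:>12.4g} {res.f_t_dim:>10.4f} "
        f"{res.ec50_model:>12.4g} {res.fold:>10.1f}"
    )

print(
    "\nA tether shorter than the site separation cannot bridge, leaving only\n"
    "the statistical factor of 2; once it spans, the molar-scale effective\n"
    "concentration drives hundreds-fold EC50 gains that fade slowly (~1/rho^1.5)."
)
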