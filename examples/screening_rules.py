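"""Back-of-the-envelope screening rules for homodimer campaigns.

The effective dissociation constant of a well-tethered homodimer scales as
the monomer K_D to the 3/2 power (molar scale); equivalently the dimer's
binding free energy is 1.5x the monomer's.  This script applies the rule to
published monomer affinities and prints the predicted best-case dimers.
"""

from avidity import worked_examples
from avidity.irreversible import best_attainable_affinity, dimer_dg_prediction

print(worked_examples().to_string(index=False))

print(
    "\ne.g. a 70 nM monomer can reach at best "
    f"{best_attainable_affinity(70e-9) * 1e12:.0f} pM as a homodimer, and a "
    f"-9.6 kcal/mol monomer predicts a {dimer_dg_prediction(-9.6):.1f} kcal/mol dimer.\n"
    "Observed affinities beating these ceilings imply extra interactions\n"
    "(e.g. tether-protein contacts); large shortfalls imply a bad linker length."
)
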