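"""The pairwise force field on minimal two-atom systems.

Places single receptor/ligand atoms at chosen separations and prints each
energy term, to show where the minima of the 12-6, 12-10, screened-Coulomb
and Gaussian-desolvation terms sit.
"""

from abscan import interaction_energy
from abscan.params import combine_lj
from abscan.synth import make_pair_fixture

r_cc, eps_cc = combine_lj("C", "C")
print(f"C-C Lennard-Jones minimum at Rij = {r_cc:.2f} A (well depth {eps_cc:.3f}):")
for r in (r_cc, 1.25 * r_cc, 2 * r_cc, 9.0):
    receptor, ligand = make_pair_fixture("C", "C", r)
    e = interaction_energy(receptor, ligand)
    print(f"  r = {r:5.2f} A  vdw = {e.vdw:+.5f} kcal/mol (weighted)")

print("polar H vs carbonyl O (hydrogen bond, 12-10 term, minimum at 1.9 A):")
for r in (1.7, 1.9, 2.5, 3.5):
    receptor, ligand = make_pair_fixture("HD", "OA", r, 0.21, -0.40)
    e = interaction_energy(receptor, ligand)
    print(f"  r = {r:4.1f} A  hbond = {e.hbond:+.4f}  elec = {e.elec:+.4f}  "
          f"total = {e.total:+.4f} kcal/mol")

print("unit charges across the sigmoidal dielectric (screening grows with r):")
for r in (2.0, 4.0, 6.0):
    receptor, ligand = make_pair_fixture("N", "OA", r, 1.0, -1.0)
    print(f"  r = {r:3.1f} A  elec = {interaction_energy(receptor, ligand).elec:+.4f} kcal/mol")
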