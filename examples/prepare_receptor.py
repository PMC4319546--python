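"""Receptor preparation: typing, PEOE charges, united-atom merge.

Prepares a single serine residue and prints the per-atom AutoDock types and
Gasteiger (PEOE) partial charges, showing the united-atom convention:
carbon-bound hydrogens are merged into their parent carbon, polar hydrogens
survive as HD donors.
"""

from abscan.model import Residue, Structure
from abscan.prep import charge_type_table, prepare_receptor
from abscan.synth import ccd_residue_atoms

serine = Structure([Residue("A", 1, "SER", "", ccd_residue_atoms("SER"))])
print(f"all-atom serine: {serine.n_atoms} atoms")
prepared = prepare_receptor(serine)
print(f"prepared (united-atom): {prepared.n_atoms} atoms")
print(charge_type_table(prepared))
total = sum(a.partial_charge for a in prepared.atoms())
print(f"net charge {total:+.6f} e (conserved through the merge; "
      f"OG is an OA acceptor, HG/H are HD donors)")
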