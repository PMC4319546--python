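"""Scan a real protein-ligand complex from a local PDB file.

Reproduces the published-style analysis on a user-supplied structure, e.g.
the steroid-bound aldo-keto reductase (PDB entry 1AFS, testosterone ligand
``TES``) or the trimethylguanosine synthase / m7GTP complex (3GDH):

    python examples/case_study.py --pdb 1afs.pdb --ligand TES:A:300 --out scan_1afs

Download the entry yourself (e.g. from https://files.rcsb.org) — no network
access is assumed here. The printed ranking nominates the residues whose
alanine mutation is predicted to cost the most binding energy.
"""

import argparse
import warnings

from abscan import LigandSelector, ScanConfig, alanine_scan, parse_pdb, write_reports
from abscan.site import list_ligand_candidates

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--pdb", required=True, help="local PDB file of the complex")
parser.add_argument("--ligand", default=None, help="RESNAME:CHAIN:RESSEQ")
parser.add_argument("--cutoff", type=float, default=4.5)
parser.add_argument("--threshold", type=float, default=0.5)
parser.add_argument("--out", default=None, help="optional report directory")
args = parser.parse_args()

warnings.simplefilter("ignore")
with open(args.pdb) as fh:
    structure = parse_pdb(fh)

if args.ligand:
    ligand = LigandSelector.parse(args.ligand)
else:
    candidates = list_ligand_candidates(structure)
    ligand = candidates[0]
    print(f"candidates: {', '.join(map(str, candidates))}; scanning {ligand}")

result = alanine_scan(structure, ligand,
                      ScanConfig(cutoff=args.cutoff, threshold=args.threshold),
                      verbose=True)
print(f"\nwild-type interaction energy {result.E_wt_total:.3f} kcal/mol; "
      f"ranked contributions:")
for rec in result.records:
    if rec.skipped:
        print(f"  {rec.label:<14s} skipped ({rec.skip_reason})")
    else:
        mark = "  <- hotspot" if rec.hotspot else ""
        print(f"  {rec.label:<14s} ddG = {rec.ddG:+7.3f} kcal/mol{mark}")
if args.out:
    write_reports(result, args.out)
    print(f"reports in {args.out}/")
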