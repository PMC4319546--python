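# Methods

## Scope and model

`abscan` estimates per-residue contributions to protein–ligand binding by
computational alanine scanning: each binding-site residue is truncated to
alanine and the complex is rescored with a pairwise semi-empirical force
field at the fixed input pose. The statistic reported per residue is
ΔΔG = E_mut − E_wt on the intermolecular interaction score. Two modelling
assumptions underlie the whole approach, and both are enforced rather than
hoped for: (a) the point mutation does not perturb the fold — guaranteed
because truncation deletes atoms and moves nothing else; (b) the ligand
binds the mutant in the same pose — guaranteed because the ligand
coordinates are never touched. Consequences: induced fit, side-chain
repacking, water reorganization and fold-stability effects of the mutation
are outside the model, and ΔΔG should be read as a *contact-loss* score,
not a full free-energy difference.

## Binding-site definition

A receptor residue is a site member iff the minimum over all (residue
atom, ligand atom) Euclidean distances is ≤ the cutoff. The default cutoff
is 4.5 Å. Hydrogens count on both sides when present; the definition is
deliberately literal ("any atom"), so a structure with explicit hydrogens
can include a residue that a heavy-atom-only structure would miss at the
same cutoff. Waters, monoatomic ions and hetero-recorded (modified)
residues are never site members; the supported route for water-mediated
binding is merging bridge waters into the ligand PDBQT, after which they
score as ligand atoms. Ligand candidates are multi-atom hetero groups,
largest first.

## Structure preparation

Receptor and (natively prepared) ligand go through the same pipeline:

1. **Bond inference.** Two atoms are bonded iff their distance is below
   the covalent-radius sum + 0.45 Å; a hydrogen bonds only to its nearest
   heavy atom. Bond orders are not inferred; hybridization is read from
   connectivity and local geometry (planarity of 3-coordinate centers,
   near-linearity for sp, short C=O distances for carbonyls).
2. **Polar-hydrogen completion** (receptor only). Missing backbone amide H
   and side-chain donor hydrogens of standard residues are placed at ideal
   X–H lengths (O–H 0.96 Å, N–H 1.01 Å, S–H 1.34 Å) along directions that
   balance the existing substituents; NH₂/NH₃ groups get sp²/tetrahedral
   umbrella geometries. The operation is idempotent and never duplicates
   an existing hydrogen. Nonstandard residues are left alone with a
   warning.
3. **AutoDock typing.** Aromatic carbon `A` is any carbon in a planar 5/6
   ring (mean out-of-plane deviation < 0.1 Å over the ring atoms, no
   4-coordinate member); all oxygens are acceptors `OA`; a nitrogen is a
   non-acceptor `N` when it carries a hydrogen or three or more heavy
   substituents (amide, ammonium, guanidinium, pyrrole/indole), otherwise
   an acceptor `NA`; divalent sulfur is the weak acceptor `SA`; hydrogen
   on N/O/S is the donor `HD`. Elements without force-field parameters are
   typed as their symbol and fail loudly only if they reach the scorer —
   the ligand-PDBQT route exists precisely to inject user-parametrized
   types (the reason metal ions are excluded by default: their charge
   state is not inferable from coordinates).
4. **PEOE charges.** Gasteiger–Marsili partial equalization of orbital
   electronegativity, χ = a + bq + cq², eight iterations, damping (1/2)^k,
   cation electronegativity 20.02 for H; coefficients keyed by element and
   hybridization. Formal charges seed the iteration: carboxylates −0.5 per
   O (unless the acid proton is explicitly present), Lys NZ +1 (unless
   explicitly neutral with two hydrogens), Arg +0.5 per NH, N-terminal
   ammonium +1 only when three hydrogens are present, C-terminal
   carboxylate −0.5/−0.5 only when OXT exists without HXT. Charge transfer
   only redistributes, so the total equals the summed formal charge
   exactly; the methane carbon comes out at −0.078 e, matching the
   published PEOE value and RDKit's implementation (used as a test oracle
   only).
5. **United-atom merge.** Carbon-bound hydrogens are deleted and their
   charge added to the parent carbon; polar hydrogens survive. Charge is
   conserved to machine precision.

Mutant complexes are re-prepared from scratch by the same pipeline, so
charge redistribution caused by the truncation is captured. PEOE transfer
is bond-local (eight bond hops maximum), which yields a useful exactness
property: a mutation cannot change the charge of any atom more than eight
bonds away, and a site residue sharing no atom pair with the ligand inside
the non-bonded cutoff has ΔΔG = 0.0 *exactly* (bitwise) when minimization
is off.

## Scoring function

AutoDock 4.1 bound-state parameter set throughout, stored in one constants
table (`abscan.params`) so a different revision is a data swap: per-type
(Rii, ε, V, S⁰), combination rules Rij = (Rii+Rjj)/2 and
ε_ij = √(ε_ii ε_jj), weights W_vdw = 0.1662, W_hb = 0.1209,
W_elec = 0.1406, W_sol = 0.1322. Terms, per receptor–ligand pair within
8.0 Å (hard cutoff, zero beyond):

- **12-6 dispersion/repulsion** with AutoDock's distance smoothing (the
  pair distance moves toward Rij by up to 0.25 Å), clamped at +100
  kcal/mol at collision range.
- **12-10 hydrogen bond** for HD/acceptor pairs, minimum −5.0 kcal/mol at
  1.9 Å for O/N acceptors, −1.0 at 2.5 Å for S. The angular attenuation
  AutoGrid applies on its maps is *not* reproduced: for rescoring a fixed
  pose the geometry never changes between wild type and mutant, so the
  angular factor is constant wherever both retain the donor/acceptor, and
  the distance-only term is the defensible pairwise form. This is a
  documented deviation: residues whose hydrogen bonds are strongly
  non-linear are scored slightly too favorably on both sides of the
  difference.
- **Screened Coulomb** with the Mehler–Solmajer sigmoidal dielectric
  (A = −8.5525, ε₀ = 78.4, λ = 0.003627, k = 7.7839) and the factor
  332.06363 kcal·Å/(mol·e²).
- **Gaussian desolvation** (S_i V_j + S_j V_i)·exp(−r²/2σ²), σ = 3.6 Å,
  S = S⁰ + 0.01097|q|.

Receptor-internal energy and the torsional entropy term are not computed:
both are identical (ligand) or nearly identical (receptor) between wild
type and mutant at fixed pose and cancel in ΔΔG. The neighbor-list scorer
is tested to agree with the all-pairs double loop to 1e−9.

## Mutagenesis and model quality

Truncation keeps N, CA, C, O, (OXT), CB and backbone hydrogens, deletes
everything else in the residue, renames it ALA, and rescales the existing
CA→CB vector to the ideal 1.53 Å (or rebuilds CB tetrahedrally if absent).
ALA is skipped as the identity; GLY is skipped because the mutation would
*add* atoms and thus invent coordinates; PRO is mutated with a ring-opening
warning; nonstandard residues are skipped and reported. Skips appear in the
output as flagged records, not errors.

Model quality is a steric-clash count: a clash is a non-bonded pair closer
than 0.6 × the vdW-radius sum, where "non-bonded" is decided on a
chemically plausible bond graph (bonds within a residue, across peptide
links, disulfides) rather than raw geometric inference — otherwise a
severe overlap would masquerade as a covalent bond and hide itself. Since
truncation removes atoms from a valid structure it cannot create clashes;
the metric certifies that, and guards the optional minimizer. This is a
deliberately simple stand-in for a statistical-potential quality score: the
contract it serves is rejecting broken models, and for deletion-only
mutants the clash count is the failure mode that exists.

The optional local minimizer (off by default, since truncation alone meets
the model's assumptions) relieves residual overlap on a soft-sphere
repulsive potential (target 0.75 × vdW sum): up to 200 gradient-descent
iterations with a 0.001 Å convergence shift, then up to 200
annealing-style steps with seeded, decaying random kicks. Only atoms
within 5 Å of the mutated residue move; the ligand never moves; a step
size growing tenfold over ten iterations aborts with a divergence flag.
Deterministic for a given seed.

## Synthetic complexes

The generator arranges chemically complete residue templates (ideal
coordinates from the Chemical Component Dictionary, with N/C-terminal caps
so each residue is a closed molecule) on a sphere around a ligand template.
Contact residues are translated along their placement direction until
their minimum atom distance to the ligand equals the contact distance
(3.5 Å default, bisection to ~1e−6 Å); non-contacts sit at 7.5 Å, outside
the 4.5 Å cutoff. By default side chains are oriented to point at the
ligand, as in a real pocket. The realized contact set is re-measured at
build time and must equal the requested one. Residues are spatially
separated rather than peptide-linked: this keeps every residue's chemistry
self-contained (well-defined PEOE, no dangling valences) and makes the
exact-contact-set guarantee satisfiable; the cost is that backbone-mediated
effects between site residues are absent from the synthetic tests.

What the toys do show: parsing/writing fidelity, typing and charge rules,
site detection against brute force, exact skip/zero identities, the sign
and decomposition of ΔΔG, determinism of the whole pipeline. What they do
not show: performance on folded proteins with buried pockets, where ΔΔG
magnitudes are several times larger (the synthetic shell touches the
ligand only at its rim), crystallographic disorder, or real water
networks. The acceptance scenario (10 residues around testosterone, 7 in
contact at 3.0 Å, seed-controlled orientations) was chosen once as a
mixed, realistic rim: aromatic, polar, charged and aliphatic side chains,
producing both signs of ΔΔG.

## Numerical choices and edge cases

- Alt-locs: highest occupancy wins, ties to the alphabetically first id;
  multi-MODEL files keep the first model with a warning.
- Malformed fixed-width records are skipped with the line number; a file
  with no coordinate records at all is an error.
- PDBQT: AutoDock4 column layout (charge 71–76, type 78–79); the
  ROOT/BRANCH torsion tree is ignored because the pose is never searched.
- Energies are accumulated pair-by-pair in a fixed (receptor-major)
  order; CSV output uses fixed 6-decimal formatting. Identical inputs,
  configuration and seed therefore give bitwise-identical reports.
- Hotspot classification is boundary-inclusive (ΔΔG ≥ threshold, default
  0.5 kcal/mol).
- The scan performs one wild-type scoring plus one scoring per non-skipped
  site residue.

## Known limitations

Single mutations only (no double-mutant cycles); no rotamer repacking or
backbone relaxation; no pKa prediction — protonation follows residue
identity and explicit hydrogens; metal ions and exotic elements require a
user-prepared ligand PDBQT with explicit charges; the distance-only
hydrogen-bond term slightly overcredits bent hydrogen bonds; scores are
rim-of-site contact losses, calibrated by the force field's empirical
weights, not absolute binding free energies.
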