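"""Alanine point mutants by side-chain truncation, plus stereochemical QC.

A mutant keeps the backbone and Cβ of the target residue and deletes every
side-chain atom beyond Cβ (hydrogens included). Alanine truncation needs no
rotamer search, leaves every other atom untouched, and so respects the two
modelling assumptions of the scan: the point mutation does not perturb the
fold, and the ligand pose is unchanged. Model quality is certified with a
steric-clash metric; an optional seeded soft-sphere minimizer can relieve
clashes locally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .bonds import infer_bonds
from .model import Atom, Residue, Structure, format_rid
from .params import (
    ALA_ALLOWED_ATOMS,
    BACKBONE_H_NAMES,
    CLASH_FACTOR,
    SIDE_CHAIN_BEYOND_CB,
    vdw_radius,
)

__all__ = ["MutantModel", "ClashReport", "MutationSkipped", "mutate_to_alanine",
           "find_clashes", "minimize_local", "model_quality"]

CB_BOND_LENGTH = 1.53  # Angstrom, ideal CA-CB


class MutationSkipped(Exception):
    """Residue cannot (ALA) or need not (GLY, nonstandard) be mutated."""

    def __init__(self, rid, reason: str):
        self.rid = rid
        self.reason = reason
        super().__init__(f"{format_rid(rid)}: {reason}")


@dataclass
class ClashReport:
    n_clashes: int = 0
    worst_overlap: float = 0.0  # Angstrom below the clash threshold
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def poor(self) -> bool:
        return self.n_clashes > 0


@dataclass
class MutantModel:
    structure: Structure
    mutated: tuple[str, int, str]
    removed_atoms: list[str]
    clash_report: ClashReport = field(default_factory=ClashReport)
    minimized: bool = False
    minimization_diverged: bool = False


# cross-residue atom-name pairs exempt across a peptide link (1-2 and 1-3)
_PEPTIDE_LINK_PAIRS = frozenset({
    frozenset(("C", "N")), frozenset(("C", "CA")), frozenset(("C", "H")),
    frozenset(("O", "N")), frozenset(("CA", "N")), frozenset(("C", "CD")),
})


def _exclusion_set(probe: Structure) -> set[tuple[int, int]]:
    """Index pairs exempt from steric checks: 1-2 and 1-3 pairs of the
    chemically plausible bond graph.

    Geometric bond inference alone would also "bond" severely overlapping
    atoms and hide exactly the clashes being looked for, so inferred bonds
    are kept only where chemistry allows them: within one residue, across a
    peptide link between consecutive residues of the same chain, or a
    disulfide SG-SG pair.
    """
    atoms = probe.atoms()
    res_of: list[int] = []
    for ri, res in enumerate(probe.residues):
        res_of.extend([ri] * len(res.atoms))
    bonds = infer_bonds(probe)
    allowed: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for i, j in bonds.edges():
        ri, rj = res_of[i], res_of[j]
        ok = False
        if ri == rj:
            ok = True
        elif abs(ri - rj) == 1 and \
                probe.residues[ri].chain_id == probe.residues[rj].chain_id:
            ok = frozenset((atoms[i].name, atoms[j].name)) in _PEPTIDE_LINK_PAIRS
        if not ok and atoms[i].name == "SG" and atoms[j].name == "SG":
            ok = True  # disulfide bridge
        if ok:
            allowed[i].add(j)
            allowed[j].add(i)
    excluded: set[tuple[int, int]] = set()
    for i, nbrs in allowed.items():
        for j in nbrs:
            excluded.add(tuple(sorted((i, j))))
            for k in allowed[j]:
                if k != i:
                    excluded.add(tuple(sorted((i, k))))
    return excluded


def find_clashes(structure: Structure, ligand_atoms: list[Atom] | None = None) -> ClashReport:
    """Steric clashes: non-bonded pairs closer than 0.6x the vdW-radius sum.

    Pairs that are covalently bonded or share a bonded neighbor (1-2 and 1-3
    pairs of the chemically plausible bond graph) are exempt. If
    ``ligand_atoms`` is given, those atoms join the check so protein-ligand
    overlap is caught too.
    """
    probe = structure.copy()
    if ligand_atoms:
        probe.residues.append(Residue("~", 9999, "LIG", "",
                                      [a.copy() for a in ligand_atoms]))
    atoms = probe.atoms()
    if len(atoms) < 2:
        return ClashReport()
    excluded = _exclusion_set(probe)
    coords = np.array([a.coords for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])

    tree = cKDTree(coords)
    max_thresh = CLASH_FACTOR * 2.0 * radii.max()
    pairs = tree.query_pairs(r=max_thresh, output_type="ndarray")
    report = ClashReport()
    for i, j in pairs:
        i, j = int(i), int(j)
        if tuple(sorted((i, j))) in excluded:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        thresh = CLASH_FACTOR * (radii[i] + radii[j])
        if d < thresh:
            report.n_clashes += 1
            report.pairs.append((atoms[i].serial, atoms[j].serial, d))
            report.worst_overlap = max(report.worst_overlap, thresh - d)
    return report


def _ideal_cb(res: Residue) -> np.ndarray:
    """Cβ from ideal tetrahedral geometry at CA (used when CB is absent)."""
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"residue {format_rid(res.rid)} lacks backbone atoms")
    u_n = (n.coords - ca.coords) / np.linalg.norm(n.coords - ca.coords)
    u_c = (c.coords - ca.coords) / np.linalg.norm(c.coords - ca.coords)
    bisector = -(u_n + u_c)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(u_c, u_n)
    perp /= np.linalg.norm(perp)
    # tetrahedral branch direction out of the N-CA-C plane
    direction = bisector * math.cos(math.radians(54.75)) + perp * math.sin(math.radians(54.75))
    return ca.coords + CB_BOND_LENGTH * direction / np.linalg.norm(direction)


def mutate_to_alanine(structure: Structure, rid: tuple[str, int, str],
                      ligand_atoms: list[Atom] | None = None) -> MutantModel:
    """Build the alanine point mutant of one residue.

    Raises :class:`MutationSkipped` for ALA (identity), GLY (would add
    atoms) and nonstandard residues. PRO is mutated with a ring-opening
    warning. Every atom outside the mutated residue is bitwise untouched.
    """
    res = structure.get_residue(rid)
    if res is None:
        raise KeyError(f"residue {format_rid(rid)} not found")
    if res.res_name == "ALA":
        raise MutationSkipped(rid, "already alanine")
    if res.res_name == "GLY":
        raise MutationSkipped(rid, "glycine (mutation would add atoms)")
    if res.res_name not in SIDE_CHAIN_BEYOND_CB:
        raise MutationSkipped(rid, f"nonstandard residue {res.res_name}")
    if res.res_name == "PRO":
        warnings.warn(f"{format_rid(rid)}: proline mutated to alanine opens the "
                      f"pyrrolidine ring", UserWarning, stacklevel=2)

    mutant = structure.copy()
    mres = mutant.get_residue(rid)
    beyond_cb = SIDE_CHAIN_BEYOND_CB[res.res_name]
    kept: list[Atom] = []
    removed: list[str] = []
    for a in mres.atoms:
        if a.element == "H":
            if a.name in BACKBONE_H_NAMES:
                kept.append(a)
            else:
                removed.append(a.name)  # side-chain hydrogens (incl. HB*)
        elif a.name in beyond_cb:
            removed.append(a.name)
        elif a.name in ("N", "CA", "C", "O", "CB", "OXT"):
            kept.append(a)
        else:
            removed.append(a.name)  # unexpected heavy atom beyond the ALA set
    mres.atoms = kept
    mres.res_name = "ALA"

    cb = mres.atom("CB")
    ca = mres.atom("CA")
    if ca is None:
        raise ValueError(f"residue {format_rid(rid)} lacks CA")
    if cb is not None:
        direction = cb.coords - ca.coords
        norm = np.linalg.norm(direction)
        if norm > 1e-6:
            cb.coords = ca.coords + CB_BOND_LENGTH * direction / norm
    else:
        mres.atoms.append(Atom(serial=max(a.serial for a in mutant.atoms()) + 1,
                               name="CB", element="C", coords=_ideal_cb(mres)))

    bad = {a.name for a in mres.atoms} - ALA_ALLOWED_ATOMS
    if bad:
        raise AssertionError(f"mutant residue carries non-alanine atoms {bad}")
    clashes = find_clashes(mutant, ligand_atoms)
    return MutantModel(mutant, rid, removed, clashes)


# ---------------------------------------------------------------------------
# Soft-sphere clash relief

def _soft_sphere_forces(coords: np.ndarray, radii: np.ndarray,
                        excluded: set[tuple[int, int]]) -> np.ndarray:
    """Gradient descent direction of E = sum k (r0 - r)^2 for r < r0,
    with r0 = 0.75 * (vdW radius sum)."""
    n = len(coords)
    forces = np.zeros_like(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=0.75 * 2.0 * radii.max(), output_type="ndarray")
    for i, j in pairs:
        i, j = int(i), int(j)
        if (i, j) in excluded:
            continue
        r0 = 0.75 * (radii[i] + radii[j])
        delta = coords[i] - coords[j]
        r = np.linalg.norm(delta)
        if r < 1e-6:
            delta = np.array([1.0, 0.0, 0.0])
            r = 1e-6
        if r < r0:
            f = 2.0 * (r0 - r) * delta / r
            forces[i] += f
            forces[j] -= f
    return forces


def minimize_local(model: MutantModel, ligand_atoms: list[Atom] | None = None,
                   max_cg_iterations: int = 200, min_shift: float = 0.001,
                   md_steps: int = 200, seed: int = 0,
                   mobile_radius: float = 5.0) -> MutantModel:
    """Relieve steric clashes around the mutated residue.

    Two stages on a soft-sphere repulsive potential, moving only atoms
    within ``mobile_radius`` of the mutated residue: (1) up to
    ``max_cg_iterations`` gradient-descent steps, stopping when the largest
    per-step atom shift drops below ``min_shift``; (2) ``md_steps``
    annealing-style steps with small seeded random kicks of decaying
    amplitude. Deterministic for a given seed. If the step size grows
    tenfold over ten iterations the run aborts and the unminimized model is
    returned with ``minimization_diverged`` set.
    """
    structure = model.structure.copy()
    probe = structure.copy()
    lig = [a.copy() for a in ligand_atoms] if ligand_atoms else []
    if lig:
        probe.residues.append(Residue("~", 9999, "LIG", "", lig))
    atoms = probe.atoms()
    coords = np.array([a.coords for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    excluded = _exclusion_set(probe)

    mres = structure.get_residue(model.mutated)
    site_coords = mres.coord_array()
    tree = cKDTree(coords)
    mobile_idx = sorted(set(
        i for idx_list in tree.query_ball_point(site_coords, mobile_radius)
        for i in idx_list))
    n_struct = structure.n_atoms
    mobile_idx = [i for i in mobile_idx if i < n_struct]  # ligand pose stays fixed
    if not mobile_idx:
        return model
    mobile = np.zeros(len(atoms), dtype=bool)
    mobile[mobile_idx] = True

    rng = np.random.default_rng(seed)
    step = 0.05
    shift_history: list[float] = []
    diverged = False

    def descend(kick: float) -> float:
        nonlocal coords
        forces = _soft_sphere_forces(coords, radii, excluded)
        forces[~mobile] = 0.0
        max_f = np.max(np.linalg.norm(forces, axis=1))
        if max_f < 1e-12:
            return 0.0  # no residual overlap: converged, no kick applied
        if kick > 0.0:
            forces = forces + kick * rng.standard_normal(coords.shape) * mobile[:, None]
            max_f = max(max_f, np.max(np.linalg.norm(forces, axis=1)))
        move = forces * min(step / max_f, 1.0)
        coords += move
        return float(np.max(np.linalg.norm(move, axis=1)))

    for it in range(max_cg_iterations):
        shift = descend(0.0)
        shift_history.append(shift)
        if shift < min_shift:
            break
        if len(shift_history) > 10 and shift > 10.0 * shift_history[-11] > 0:
            diverged = True
            break

    if not diverged:
        for k in range(md_steps):
            kick = 0.01 * (1.0 - k / md_steps)
            shift = descend(kick)
            if shift == 0.0:
                break

    if diverged:
        out = MutantModel(model.structure, model.mutated, model.removed_atoms,
                          model.clash_report, minimized=False,
                          minimization_diverged=True)
        return out

    # write back moved coordinates (structure atoms only)
    for i, a in enumerate(structure.atoms()):
        a.coords = coords[i].copy()
    report = find_clashes(structure, ligand_atoms)
    return MutantModel(structure, model.mutated, model.removed_atoms, report,
                       minimized=True)


def model_quality(model: MutantModel) -> dict:
    """Clash-based model-quality summary; ``poor`` flags any residual clash."""
    rep = model.clash_report
    return {"n_clashes": rep.n_clashes, "worst_overlap": round(rep.worst_overlap, 3),
            "poor": rep.poor}
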