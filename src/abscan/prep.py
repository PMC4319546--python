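"""Force-field preparation: AutoDock atom typing, PEOE partial charges,
polar-hydrogen completion and the united-atom merge.

The contract mirrors AutoDock's receptor/ligand preparation with its default
flags: Gasteiger (PEOE) charges on the all-atom model, nonpolar hydrogens
merged into their parent carbons, polar hydrogens kept explicit, and missing
polar hydrogens of standard residues added at ideal geometry
(``check_hydrogens`` behaviour).
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np

from .bonds import BondGraph, infer_bonds
from .model import Atom, LigandModel, LigandSelector, Residue, Structure
from .params import (
    AD4_ATOM_PARAMS,
    IDEAL_XH_BOND,
    PEOE_COEFFS,
    PEOE_DAMPING,
    PEOE_H_CATION_CHI,
    PEOE_ITERATIONS,
    SIDECHAIN_FORMAL_CHARGES,
    SIDECHAIN_POLAR_H,
    normalize_element,
)

__all__ = [
    "assign_autodock_types",
    "assign_gasteiger_charges",
    "unite_nonpolar_hydrogens",
    "check_hydrogens",
    "prepare_receptor",
    "prepare_ligand",
    "charge_type_table",
]

AROMATIC_RING_SIZES = (5, 6)
AROMATIC_PLANARITY_TOL = 0.1  # Angstrom, mean out-of-plane deviation


class PrepWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Ring perception and hybridization

def _ring_systems(graph: BondGraph, atoms: list[Atom]) -> list[list[int]]:
    """Candidate aromatic rings: 5/6-membered cycles over heavy atoms."""
    g = nx.Graph()
    heavy = [i for i, a in enumerate(atoms) if not a.is_hydrogen]
    g.add_nodes_from(heavy)
    for i, j in graph.edges():
        if not atoms[i].is_hydrogen and not atoms[j].is_hydrogen:
            g.add_edge(i, j)
    rings = []
    for cyc in nx.minimum_cycle_basis(g):
        if len(cyc) in AROMATIC_RING_SIZES:
            rings.append(sorted(cyc))
    return rings


def _mean_out_of_plane(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    # smallest singular direction is the plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return float(np.mean(np.abs(centered @ normal)))


def _aromatic_atoms(structure_atoms: list[Atom], graph: BondGraph) -> set[int]:
    aromatic: set[int] = set()
    for ring in _ring_systems(graph, structure_atoms):
        coords = np.array([structure_atoms[i].coords for i in ring])
        if _mean_out_of_plane(coords) >= AROMATIC_PLANARITY_TOL:
            continue
        # sp3 ring atoms (4 substituents) disqualify the ring
        if any(graph.degree(i) > 3 for i in ring):
            continue
        aromatic.update(ring)
    return aromatic


def _point_plane_distance(p: np.ndarray, pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    n = np.linalg.norm(normal)
    if n < 1e-9:
        return 0.0
    return float(abs(np.dot(p - pts[0], normal / n)))


def _hybridization(i: int, atoms: list[Atom], graph: BondGraph,
                   aromatic: set[int]) -> str | None:
    a = atoms[i]
    el = normalize_element(a.element)
    nbrs = graph.neighbors(i)
    deg = len(nbrs)
    coords = a.coords
    nbr_coords = np.array([atoms[j].coords for j in nbrs]) if nbrs else np.zeros((0, 3))
    if el == "C":
        if i in aromatic:
            return "sp2"
        if deg >= 4:
            return "sp3"
        if deg == 3:
            return "sp2" if _point_plane_distance(coords, nbr_coords) < 0.25 else "sp3"
        if deg == 2:
            v1 = nbr_coords[0] - coords
            v2 = nbr_coords[1] - coords
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if cosang < -math.cos(math.radians(30)):  # near-linear
                return "sp"
            # short bond to oxygen marks a carbonyl carbon missing substituent H
            for j in nbrs:
                if normalize_element(atoms[j].element) == "O" and \
                        np.linalg.norm(atoms[j].coords - coords) < 1.30:
                    return "sp2"
            return "sp3"
        return "sp3"
    if el == "N":
        if i in aromatic:
            return "sp2"
        if deg >= 4:
            return "sp3"
        if deg == 3:
            return "sp2" if _point_plane_distance(coords, nbr_coords) < 0.25 else "sp3"
        if deg == 2:
            return "sp2"
        return "sp"
    if el == "O":
        if deg >= 2:
            return "sp3"
        if deg == 1:
            j = nbrs[0]
            d = np.linalg.norm(atoms[j].coords - coords)
            return "sp2" if d < 1.30 else "sp3"
        return "sp3"
    return None


# ---------------------------------------------------------------------------
# AutoDock atom typing

def assign_autodock_types(structure: Structure, bonds: BondGraph) -> Structure:
    """Assign an AutoDock atom type to every atom (in place; also returned).

    Rules: aromatic carbons (planar 5/6-ring) -> A, other carbon -> C;
    oxygen -> OA; nitrogen with an attached H or three-plus heavy partners
    -> N, otherwise (lone pair available) -> NA; divalent sulfur -> SA,
    higher-valent -> S; hydrogen on N/O/S -> HD, on carbon -> H; halogens
    and phosphorus map directly.
    """
    atoms = structure.atoms()
    aromatic = _aromatic_atoms(atoms, bonds)
    for i, a in enumerate(atoms):
        el = normalize_element(a.element)
        nbrs = bonds.neighbors(i)
        if el == "C":
            a.ad_type = "A" if i in aromatic else "C"
        elif el == "O":
            a.ad_type = "OA"
        elif el == "N":
            has_h = any(atoms[j].is_hydrogen for j in nbrs)
            heavy_deg = sum(1 for j in nbrs if not atoms[j].is_hydrogen)
            a.ad_type = "N" if (has_h or heavy_deg >= 3 or len(nbrs) >= 4) else "NA"
        elif el == "S":
            a.ad_type = "SA" if len(nbrs) <= 2 else "S"
        elif el == "H":
            parent_el = normalize_element(atoms[nbrs[0]].element) if nbrs else "C"
            a.ad_type = "HD" if parent_el in ("N", "O", "S") else "H"
        elif el in ("F", "P", "I"):
            a.ad_type = el
        elif el in ("CL", "BR"):
            a.ad_type = el.capitalize()
        else:
            a.ad_type = a.element
            warnings.warn(
                f"atom {a.serial} {a.name!r}: element {a.element!r} has no AutoDock "
                f"parameters; typed as its element symbol", PrepWarning, stacklevel=2)
    return structure


# ---------------------------------------------------------------------------
# PEOE (Gasteiger-Marsili) charges

def _seed_formal_charges(structure: Structure, bonds: BondGraph) -> np.ndarray:
    atoms = structure.atoms()
    index_of = {id(a): i for i, a in enumerate(atoms)}
    q = np.zeros(len(atoms))

    def n_attached_h(i: int) -> int:
        return sum(1 for j in bonds.neighbors(i) if atoms[j].is_hydrogen)

    for res in structure.residues:
        if not res.is_standard_aa:
            continue
        charges = SIDECHAIN_FORMAL_CHARGES.get(res.res_name)
        if charges:
            # skip if the neutralizing acid proton is explicitly present
            acid_h = {"ASP": "HD2", "GLU": "HE2"}.get(res.res_name)
            if acid_h is None or res.atom(acid_h) is None:
                if res.res_name == "LYS":
                    nz = res.atom("NZ")
                    if nz is not None and n_attached_h(index_of[id(nz)]) == 2:
                        continue  # explicitly neutral amine
                for name, fc in charges.items():
                    a = res.atom(name)
                    if a is not None:
                        q[index_of[id(a)]] += fc
        # termini: protonated N-terminus, deprotonated C-terminus
        n = res.atom("N")
        if n is not None and n_attached_h(index_of[id(n)]) >= 3:
            q[index_of[id(n)]] += 1.0
        oxt = res.atom("OXT")
        if oxt is not None and res.atom("HXT") is None:
            q[index_of[id(oxt)]] += -0.5
            o = res.atom("O")
            if o is not None:
                q[index_of[id(o)]] += -0.5
    return q


def assign_gasteiger_charges(structure: Structure, bonds: BondGraph) -> Structure:
    """Compute PEOE partial charges (in place; also returned).

    Iterative partial equalization of orbital electronegativity:
    chi_i = a + b q_i + c q_i^2; at iteration k each bond transfers
    (chi_j - chi_i) / chi^+ * damping^k of an electron toward the more
    electronegative partner (chi^+ is the cation electronegativity of the
    donor, 20.02 for H). Eight iterations with damping 1/2. Formal charges
    on ionized side chains and termini seed the iteration, so the total
    charge equals the summed formal charge exactly.
    """
    atoms = structure.atoms()
    aromatic = _aromatic_atoms(atoms, bonds)
    n = len(atoms)
    q = _seed_formal_charges(structure, bonds)

    abc = []
    chiplus = np.zeros(n)
    missing: list[int] = []
    for i, a in enumerate(atoms):
        el = normalize_element(a.element)
        hyb = _hybridization(i, atoms, bonds, aromatic)
        coeffs = PEOE_COEFFS.get((el, hyb)) or PEOE_COEFFS.get((el, None))
        if coeffs is None:
            missing.append(i)
            warnings.warn(
                f"atom {a.serial} {a.name!r}: no PEOE coefficients for element "
                f"{a.element!r}; charge left at its formal value", PrepWarning,
                stacklevel=2)
            abc.append(None)
            continue
        abc.append(coeffs)
        chiplus[i] = PEOE_H_CATION_CHI if el == "H" else sum(coeffs)

    edges = [(i, j) for i, j in bonds.edges()
             if abc[i] is not None and abc[j] is not None]
    damp = 1.0
    for _ in range(PEOE_ITERATIONS):
        damp *= PEOE_DAMPING
        chi = np.array([
            (abc[i][0] + abc[i][1] * q[i] + abc[i][2] * q[i] * q[i])
            if abc[i] is not None else 0.0
            for i in range(n)])
        dq = np.zeros(n)
        for i, j in edges:
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chiplus[i] * damp
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chiplus[j] * damp
                dq[j] += t
                dq[i] -= t
        q += dq

    for i, a in enumerate(atoms):
        a.partial_charge = float(q[i])
    return structure


# ---------------------------------------------------------------------------
# United-atom merge

def unite_nonpolar_hydrogens(structure: Structure, bonds: BondGraph) -> Structure:
    """Merge carbon-bound hydrogens into their parent carbon (charge summed).

    Polar hydrogens (on N/O/S) survive. Returns a new structure; total
    charge is conserved exactly because the merge only moves charge.
    """
    atoms = structure.atoms()
    drop: set[int] = set()
    extra_charge: dict[int, float] = {}
    for i, a in enumerate(atoms):
        if not a.is_hydrogen:
            continue
        nbrs = bonds.neighbors(i)
        if not nbrs:
            warnings.warn(
                f"hydrogen {a.serial} {a.name!r} has no parent atom; removed and "
                f"its charge ({a.partial_charge}) dropped", PrepWarning, stacklevel=2)
            drop.add(i)
            continue
        parent = nbrs[0]
        if normalize_element(atoms[parent].element) == "C":
            drop.add(i)
            extra_charge[parent] = extra_charge.get(parent, 0.0) + (a.partial_charge or 0.0)

    out = Structure([], title=structure.title, source_format=structure.source_format)
    idx = 0
    for res in structure.residues:
        new_res = Residue(res.chain_id, res.res_seq, res.res_name, res.i_code)
        for a in res.atoms:
            if idx not in drop:
                new_atom = a.copy()
                if idx in extra_charge:
                    new_atom.partial_charge = (a.partial_charge or 0.0) + extra_charge[idx]
                new_res.atoms.append(new_atom)
            idx += 1
        if new_res.atoms:
            out.residues.append(new_res)
    return out


# ---------------------------------------------------------------------------
# Polar-hydrogen completion

def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (v * math.cos(angle) + np.cross(axis, v) * math.sin(angle)
            + axis * np.dot(axis, v) * (1.0 - math.cos(angle)))


def _hydrogen_directions(parent: np.ndarray, nbr_coords: np.ndarray, n_h: int) -> list[np.ndarray]:
    """Deterministic ideal directions for n_h hydrogens on a heavy atom."""
    if len(nbr_coords) == 0:
        base = np.array([0.0, 0.0, 1.0])
    else:
        units = [(c - parent) / np.linalg.norm(c - parent) for c in nbr_coords]
        s = -np.sum(units, axis=0)
        norm = np.linalg.norm(s)
        base = s / norm if norm > 1e-6 else _perpendicular(units[0])
    if n_h == 1:
        return [base]
    if len(nbr_coords) >= 1:
        axis = (nbr_coords[0] - parent)
    else:
        axis = _perpendicular(base)
    if n_h == 2:
        # sp2-like pair straddling the base direction in the plane normal to axis
        perp = _perpendicular(axis)
        d1 = _rotate(base, perp, math.radians(30.0))
        d2 = _rotate(base, perp, math.radians(-30.0))
        return [d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2)]
    # n_h == 3: tetrahedral umbrella around the base direction
    u = axis / np.linalg.norm(axis)
    tilt = _rotate(base, _perpendicular(u), math.radians(180.0 - 109.47))
    dirs = [_rotate(tilt, base, math.radians(120.0 * k)) for k in range(3)]
    return [d / np.linalg.norm(d) for d in dirs]


def check_hydrogens(structure: Structure, bonds: BondGraph | None = None) -> Structure:
    """Add missing polar hydrogens of standard residues at ideal geometry.

    Backbone amide H (non-proline, non-N-terminal) and the side-chain donor
    hydrogens of Ser/Thr/Tyr/Cys/Trp/His/Asn/Gln/Arg/Lys are placed at the
    ideal X-H bond length along the direction that balances the existing
    substituents. Existing hydrogens are never duplicated; nonstandard
    residues are left untouched with a warning. Idempotent.
    """
    structure = structure.copy()
    if bonds is None:
        bonds = infer_bonds(structure)
    atoms = structure.atoms()
    index_of = {id(a): i for i, a in enumerate(atoms)}
    next_serial = max((a.serial for a in atoms), default=0) + 1

    # previous-residue carbonyl C for backbone amide placement
    prev_c: dict[tuple, Atom] = {}
    prev: Residue | None = None
    for res in structure.residues:
        if prev is not None and prev.chain_id == res.chain_id and not res.is_hetero:
            c = prev.atom("C")
            if c is not None:
                prev_c[res.rid] = c
        prev = res

    for res in structure.residues:
        if res.is_hetero:
            continue
        if not res.is_standard_aa:
            warnings.warn(
                f"nonstandard residue {res.res_name} {res.chain_id}:{res.res_seq} "
                f"left unprotonated", PrepWarning, stacklevel=2)
            continue
        additions: list[tuple[str, str, int]] = []  # (H name, parent name, count group)
        n = res.atom("N")
        if (res.res_name != "PRO" and n is not None and res.atom("H") is None
                and not any(res.atom(x) for x in ("H1", "H2", "H3", "HN"))
                and res.rid in prev_c):
            additions.append(("H", "N", 1))
        for h_name, parent_name in SIDECHAIN_POLAR_H.get(res.res_name, []):
            if res.atom(h_name) is None and res.atom(parent_name) is not None:
                additions.append((h_name, parent_name, 1))

        # group simultaneous hydrogens on the same parent (NH2, NH3)
        by_parent: dict[str, list[str]] = {}
        for h_name, parent_name, _ in additions:
            by_parent.setdefault(parent_name, []).append(h_name)

        for parent_name, h_names in by_parent.items():
            parent = res.atom(parent_name)
            pi = index_of[id(parent)]
            nbr_coords = np.array([atoms[j].coords for j in bonds.neighbors(pi)
                                   if not atoms[j].is_hydrogen])
            existing_h = [atoms[j] for j in bonds.neighbors(pi) if atoms[j].is_hydrogen]
            # total hydrogens the site should carry = existing + missing
            n_new = len(h_names)
            occupied = np.array([h.coords for h in existing_h])
            context = np.vstack([nbr_coords, occupied]) if len(occupied) else nbr_coords
            if parent_name == "N" and res.rid in prev_c and parent.name == "N":
                cprev = prev_c[res.rid]
                context = np.vstack([context, cprev.coords[None, :]]) \
                    if len(context) else cprev.coords[None, :]
            dirs = _hydrogen_directions(parent.coords, context, n_new)
            length = IDEAL_XH_BOND.get(normalize_element(parent.element), 1.0)
            for h_name, d in zip(h_names, dirs):
                res.atoms.append(Atom(
                    serial=next_serial, name=h_name, element="H",
                    coords=parent.coords + length * d))
                next_serial += 1
    return structure


# ---------------------------------------------------------------------------
# High-level preparation pipelines

def prepare_receptor(structure: Structure, add_polar_h: bool = True) -> Structure:
    """Full receptor preparation: polar-H completion, typing, PEOE charges,
    united-atom merge. Returns a new scoreable structure."""
    receptor = structure.receptor_only()
    if add_polar_h:
        receptor = check_hydrogens(receptor)
    bonds = infer_bonds(receptor)
    assign_autodock_types(receptor, bonds)
    assign_gasteiger_charges(receptor, bonds)
    return unite_nonpolar_hydrogens(receptor, bonds)


def prepare_ligand(residues: list[Residue],
                   selector: LigandSelector | None = None) -> LigandModel:
    """Type and charge a hetero group natively (when no ligand PDBQT is given)."""
    sub = Structure([r.copy() for r in residues])
    bonds = infer_bonds(sub)
    assign_autodock_types(sub, bonds)
    assign_gasteiger_charges(sub, bonds)
    sub = unite_nonpolar_hydrogens(sub, bonds)
    atoms = sub.atoms()
    model = LigandModel([a.copy() for a in atoms], selector=selector,
                        includes_bridge_waters=any(r.is_water for r in residues))
    model.validate()
    return model


def charge_type_table(structure: Structure) -> str:
    """Tab-separated per-atom debug dump: residue, atom, AD type, charge."""
    rows = ["chain\tres_seq\tres_name\tatom\tad_type\tcharge"]
    for res in structure.residues:
        for a in res.atoms:
            charge = "" if a.partial_charge is None else f"{a.partial_charge:.4f}"
            rows.append(f"{res.chain_id}\t{res.res_seq}\t{res.res_name}\t"
                        f"{a.name}\t{a.ad_type or ''}\t{charge}")
    return "\n".join(rows) + "\n"
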