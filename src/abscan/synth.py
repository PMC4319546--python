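"""Synthetic protein-ligand complexes with known geometry and energetics.

Every stage of the scan is testable without downloads: residues are taken
as ideal-geometry all-atom templates from the Chemical Component Dictionary
bundled with biotite (each a chemically complete molecule with N/C-terminal
caps), arranged deterministically around a ligand so that a chosen subset
of residues — and only that subset — lies within the binding-site cutoff.
These are not folded conformations; they are controlled testbeds whose
contact structure is known by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Atom, LigandModel, LigandSelector, Residue, Structure
from .site import DEFAULT_CUTOFF

__all__ = ["ToySpec", "ToyPlacementError", "make_toy_complex", "make_pair_fixture",
           "ccd_residue_atoms"]

DEFAULT_RESIDUE_CYCLE = ("SER", "LEU", "TRP", "ASP", "LYS", "PHE", "THR", "TYR",
                         "VAL", "ASN", "ARG", "MET")

# element behind each AutoDock type, for minimal pair fixtures
AD_TYPE_ELEMENT = {
    "C": "C", "A": "C", "N": "N", "NA": "N", "OA": "O", "S": "S", "SA": "S",
    "H": "H", "HD": "H", "F": "F", "Cl": "Cl", "Br": "Br", "I": "I", "P": "P",
}


class ToyPlacementError(ValueError):
    """The requested contact pattern cannot be realized geometrically."""


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a deterministic synthetic complex.

    ``contact_residues`` are 1-based residue sequence numbers placed so
    their minimum atom distance to the ligand is ``contact_distance``
    (inside the cutoff); all others sit at ``noncontact_distance``
    (outside it). Expansion is a pure function of the spec.
    """

    n_residues: int = 6
    residue_names: Optional[Sequence[str]] = None
    ligand_ccd: Optional[str] = "IPA"  # CCD id of the ligand template
    ligand_atoms: Optional[Sequence[tuple[str, Sequence[float], float]]] = None
    contact_residues: Sequence[int] = field(default=())
    contact_distance: float = 3.5
    noncontact_distance: float = 7.5
    cutoff: float = DEFAULT_CUTOFF
    orient_side_chains: bool = True  # point side chains at the ligand, as in a pocket
    seed: int = 0


def ccd_residue_atoms(res_name: str, serial_start: int = 1) -> list[Atom]:
    """Ideal all-atom coordinates of a CCD component, centered at its centroid."""
    import biotite.structure.info as info

    arr = info.residue(res_name)
    if arr is None:
        raise KeyError(f"unknown CCD component {res_name!r}")
    coords = np.asarray(arr.coord, dtype=float)
    coords = coords - coords.mean(axis=0)
    atoms = []
    for k in range(len(arr)):
        el = str(arr.element[k])
        atoms.append(Atom(serial=serial_start + k, name=str(arr.atom_name[k]),
                          element=el.capitalize() if len(el) > 1 else el,
                          coords=coords[k]))
    return atoms


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


_BACKBONE_NAMES = frozenset("N CA C O OXT".split())


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-9:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic, well-separated unit vectors (golden-spiral points)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _place_at_min_distance(coords: np.ndarray, direction: np.ndarray,
                           lig_coords: np.ndarray, target: float) -> np.ndarray:
    """Translate a centered atom cloud along ``direction`` so its minimum
    distance to the ligand equals ``target`` (to ~1e-6 Å, via bisection)."""

    def min_dist(radius: float) -> float:
        shifted = coords + radius * direction
        d = np.linalg.norm(shifted[:, None, :] - lig_coords[None, :, :], axis=2)
        return float(d.min())

    lo, hi = 0.0, 60.0
    if min_dist(hi) < target:
        raise ToyPlacementError("ligand too large for placement shell")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target:
            lo = mid
        else:
            hi = mid
    return coords + 0.5 * (lo + hi) * direction


def _build_ligand_residue(spec: ToySpec) -> Residue:
    if spec.ligand_atoms is not None:
        atoms = [Atom(serial=9000 + k, name=f"{el.upper()}{k + 1}", element=el,
                      coords=np.asarray(xyz, dtype=float), is_hetero=True,
                      partial_charge=q)
                 for k, (el, xyz, q) in enumerate(spec.ligand_atoms)]
        name = "LIG"
    elif spec.ligand_ccd is not None:
        atoms = ccd_residue_atoms(spec.ligand_ccd, serial_start=9000)
        for a in atoms:
            a.is_hetero = True
        name = spec.ligand_ccd
    else:
        raise ValueError("spec needs ligand_ccd or ligand_atoms")
    return Residue("L", 1, name, "", atoms)


def make_toy_complex(spec: ToySpec) -> Structure:
    """Expand a :class:`ToySpec` into a structure with the ligand at the
    origin and residues on a sphere, contacts inside the cutoff and
    non-contacts outside it. Raises :class:`ToyPlacementError` if the
    realized contact set differs from the requested one."""
    if spec.contact_distance >= spec.cutoff:
        raise ToyPlacementError("contact_distance must be inside the cutoff")
    if spec.noncontact_distance <= spec.cutoff:
        raise ToyPlacementError("noncontact_distance must be outside the cutoff")
    contacts = set(spec.contact_residues)
    unknown = contacts - set(range(1, spec.n_residues + 1))
    if unknown:
        raise ToyPlacementError(f"contact residue numbers out of range: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    names = list(spec.residue_names) if spec.residue_names else \
        list(itertools.islice(itertools.cycle(DEFAULT_RESIDUE_CYCLE), spec.n_residues))
    if len(names) != spec.n_residues:
        raise ToyPlacementError("residue_names length must equal n_residues")

    ligand = _build_ligand_residue(spec)
    lig_coords = ligand.coord_array()

    directions = _sphere_directions(spec.n_residues)
    residues: list[Residue] = []
    serial = 1
    for i in range(1, spec.n_residues + 1):
        atoms = ccd_residue_atoms(names[i - 1], serial_start=serial)
        serial += len(atoms)
        rot = _rotation_matrix(rng)  # consumed per residue: seeded, deterministic
        coords = np.array([a.coords for a in atoms]) @ rot.T
        if spec.orient_side_chains:
            # as in a real pocket, the side chain points into the site
            atom_names = [a.name for a in atoms]
            side = [k for k, nm in enumerate(atom_names)
                    if nm not in _BACKBONE_NAMES and atoms[k].element != "H"]
            ca = atom_names.index("CA") if "CA" in atom_names else None
            if side and ca is not None:
                axis = coords[side].mean(axis=0) - coords[ca]
                norm = np.linalg.norm(axis)
                if norm > 1e-6:
                    coords = coords @ _align_rotation(axis / norm, -directions[i - 1]).T
        target = spec.contact_distance if i in contacts else spec.noncontact_distance
        coords = _place_at_min_distance(coords, directions[i - 1], lig_coords, target)
        for a, c in zip(atoms, coords):
            a.coords = c
        residues.append(Residue("A", i, names[i - 1], "", atoms))

    structure = Structure(residues + [ligand], title="synthetic toy complex")
    structure.validate()

    # certify the construction against the site detector's own definition
    realized = set()
    for res in residues:
        d = np.linalg.norm(res.coord_array()[:, None, :] - lig_coords[None, :, :], axis=2)
        if float(d.min()) <= spec.cutoff:
            realized.add(res.res_seq)
    if realized != contacts:
        raise ToyPlacementError(
            f"requested contacts {sorted(contacts)} but geometry realized {sorted(realized)}")
    return structure


def make_pair_fixture(type_i: str, type_j: str, r: float,
                      q_i: float = 0.0, q_j: float = 0.0
                      ) -> tuple[Structure, LigandModel]:
    """One receptor atom at the origin and one ligand atom at distance r:
    the minimal testbed whose energy follows the closed-form pair terms."""
    for t in (type_i, type_j):
        if t not in AD_TYPE_ELEMENT:
            raise KeyError(f"unsupported AutoDock type {t!r}")
    rec_atom = Atom(serial=1, name=AD_TYPE_ELEMENT[type_i].upper(),
                    element=AD_TYPE_ELEMENT[type_i], coords=np.zeros(3),
                    ad_type=type_i, partial_charge=q_i)
    receptor = Structure([Residue("A", 1, "UNK", "", [rec_atom])])
    lig_atom = Atom(serial=2, name=AD_TYPE_ELEMENT[type_j].upper(),
                    element=AD_TYPE_ELEMENT[type_j],
                    coords=np.array([r, 0.0, 0.0]), is_hetero=True,
                    ad_type=type_j, partial_charge=q_j)
    ligand = LigandModel([lig_atom], selector=LigandSelector("LIG", "L", 1))
    return receptor, ligand
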