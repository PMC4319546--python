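"""Covalent bond inference from geometry.

Two heavy atoms are bonded iff their distance is below the sum of covalent
radii plus a 0.45 Å tolerance. A hydrogen bonds only to its single nearest
heavy atom within that threshold (degree of H is at most 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import Structure
from .params import BOND_TOLERANCE, covalent_radius

__all__ = ["BondGraph", "infer_bonds"]

_MAX_BOND_DISTANCE = 2.0 * 1.39 + BOND_TOLERANCE  # I-I upper bound


@dataclass
class BondGraph:
    """Symmetric adjacency over atom indices (order of ``structure.atoms()``)."""

    n_atoms: int
    adjacency: dict[int, list[int]] = field(default_factory=dict)
    tolerance: float = BOND_TOLERANCE

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-bonds are not allowed")
        if j not in self.adjacency.setdefault(i, []):
            self.adjacency[i].append(j)
        if i not in self.adjacency.setdefault(j, []):
            self.adjacency[j].append(i)

    def neighbors(self, i: int) -> list[int]:
        return sorted(self.adjacency.get(i, []))

    def degree(self, i: int) -> int:
        return len(self.adjacency.get(i, []))

    def are_bonded(self, i: int, j: int) -> bool:
        return j in self.adjacency.get(i, [])

    def edges(self) -> list[tuple[int, int]]:
        return sorted((i, j) for i, nbrs in self.adjacency.items() for j in nbrs if i < j)

    @property
    def n_bonds(self) -> int:
        return len(self.edges())


def infer_bonds(structure: Structure) -> BondGraph:
    """Build the covalent bond graph of a structure from interatomic distances."""
    atoms = structure.atoms()
    graph = BondGraph(n_atoms=len(atoms))
    if len(atoms) < 2:
        return graph
    coords = np.array([a.coords for a in atoms])
    elements = [a.element for a in atoms]
    radii = np.array([covalent_radius(e) for e in elements])
    is_h = np.array([a.is_hydrogen for a in atoms])

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=_MAX_BOND_DISTANCE, output_type="ndarray")
    if pairs.size == 0:
        return graph
    dists = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    cut = radii[pairs[:, 0]] + radii[pairs[:, 1]] + BOND_TOLERANCE
    ok = (dists < cut) & (dists > 1e-6)

    # hydrogens: defer, then attach each to its nearest heavy partner only
    h_candidates: dict[int, tuple[float, int]] = {}
    for (i, j), d, keep in zip(pairs, dists, ok):
        i, j = int(i), int(j)
        if not keep:
            continue
        if is_h[i] and is_h[j]:
            continue
        if is_h[i] or is_h[j]:
            h, heavy = (i, j) if is_h[i] else (j, i)
            if h not in h_candidates or d < h_candidates[h][0]:
                h_candidates[h] = (d, heavy)
        else:
            graph.add_bond(i, j)
    for h, (_, heavy) in h_candidates.items():
        graph.add_bond(h, heavy)
    return graph
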