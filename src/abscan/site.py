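"""Binding-site definition: ligand candidates and residues within a cutoff.

A receptor residue belongs to the binding site iff the minimum Euclidean
distance over all (residue atom, ligand atom) pairs is within the cutoff
(default 4.5 Å). Hydrogens count on both sides. Waters, ions and hetero
(modified) residues are never site members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import LigandModel, LigandSelector, Residue, Structure

__all__ = ["BindingSite", "SiteResidue", "list_ligand_candidates",
           "resolve_ligand", "select_binding_site", "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 4.5  # Angstrom


class NoLigandError(ValueError):
    """The structure contains no plausible ligand group."""


@dataclass(frozen=True)
class SiteResidue:
    rid: tuple[str, int, str]
    res_name: str
    min_distance: float
    n_contact_atoms: int


@dataclass
class BindingSite:
    residues: list[SiteResidue] = field(default_factory=list)
    cutoff: float = DEFAULT_CUTOFF
    ligand: LigandSelector | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def rids(self) -> list[tuple[str, int, str]]:
        return [r.rid for r in self.residues]


def list_ligand_candidates(structure: Structure) -> list[LigandSelector]:
    """All hetero groups except waters and single-atom ions, largest first."""
    candidates: list[tuple[int, LigandSelector]] = []
    for res in structure.hetero_residues():
        if res.is_water:
            continue
        heavy = res.heavy_atoms()
        if len(heavy) <= 1:
            continue  # monoatomic ion
        candidates.append((len(heavy), LigandSelector(res.res_name, res.chain_id, res.res_seq)))
    if not candidates:
        raise NoLigandError("no ligand found: structure has no multi-atom hetero group")
    candidates.sort(key=lambda t: (-t[0], t[1].chain_id, t[1].res_seq))
    return [sel for _, sel in candidates]


def resolve_ligand(structure: Structure, selector: LigandSelector) -> Residue:
    matches = [r for r in structure.hetero_residues()
               if r.res_name == selector.res_name
               and r.chain_id == selector.chain_id
               and r.res_seq == selector.res_seq]
    if not matches:
        raise NoLigandError(f"ligand {selector} not found among hetero groups")
    if len(matches) > 1:
        raise ValueError(f"ligand selector {selector} is ambiguous ({len(matches)} matches)")
    return matches[0]


def select_binding_site(structure: Structure,
                        ligand: LigandSelector | LigandModel | Residue,
                        cutoff: float = DEFAULT_CUTOFF) -> BindingSite:
    """Receptor residues with any atom within ``cutoff`` of any ligand atom.

    ``ligand`` may be a selector (resolved against the structure), an
    already-built :class:`LigandModel` (e.g. carrying bridge waters), or a
    residue. Modified amino acids recorded as hetero groups are excluded
    from the scan list with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    selector: LigandSelector | None = None
    if isinstance(ligand, LigandSelector):
        selector = ligand
        lig_coords = resolve_ligand(structure, ligand).coord_array()
    elif isinstance(ligand, LigandModel):
        selector = ligand.selector
        lig_coords = ligand.coord_array()
    else:
        selector = LigandSelector(ligand.res_name, ligand.chain_id, ligand.res_seq)
        lig_coords = ligand.coord_array()
    if len(lig_coords) == 0:
        raise NoLigandError("ligand has no atoms")

    tree = cKDTree(lig_coords)
    members: list[SiteResidue] = []
    excluded_modified = 0
    for res in structure.residues:
        if res.is_hetero or res.is_water:
            if res.is_hetero and not res.is_water and res.res_name in _MODIFIED_AA_HINTS:
                excluded_modified += 1
            continue
        coords = res.coord_array()
        dists, _ = tree.query(coords, k=1)
        min_d = float(np.min(dists))
        if min_d <= cutoff:
            n_contact = int(np.sum(dists <= cutoff))
            members.append(SiteResidue(res.rid, res.res_name, min_d, n_contact))
    if excluded_modified:
        warnings.warn(f"{excluded_modified} modified (hetero) residue(s) near the "
                      f"ligand excluded from the scan list", UserWarning, stacklevel=2)
    members.sort(key=lambda m: m.rid)
    if not members:
        warnings.warn(f"no receptor residue within {cutoff:.2f} A of the ligand",
                      UserWarning, stacklevel=2)
    return BindingSite(members, cutoff=cutoff, ligand=selector)


# common modified amino acids worth an explicit exclusion notice
_MODIFIED_AA_HINTS = frozenset({"MSE", "SEP", "TPO", "PTR", "CSO", "MLY", "HYP", "KCX"})
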