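"""Hierarchical structure model: atoms, residues, structures, ligands.

The same atom record serves PDB and PDBQT input: PDBQT adds a partial
charge and an AutoDock atom type on top of the PDB coordinate fields.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: residue names treated as water when pruning ligand candidates / sites
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) float64, Angstrom
    alt_loc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False
    ad_type: Optional[str] = None
    partial_charge: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name!r}: coords must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self) -> "Atom":
        a = copy.copy(self)
        a.coords = self.coords.copy()
        return a


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    res_name: str
    i_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def rid(self) -> tuple[str, int, str]:
        """Residue identity triple (chain, sequence number, insertion code)."""
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def is_hetero(self) -> bool:
        return any(a.is_hetero for a in self.atoms)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_standard_aa(self) -> bool:
        return self.res_name in STANDARD_AMINO_ACIDS and not self.is_hetero

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.res_seq, self.res_name, self.i_code,
                       [a.copy() for a in self.atoms])


def format_rid(rid: tuple[str, int, str]) -> str:
    chain, seq, icode = rid
    return f"{chain}:{seq}{icode}"


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    source_format: str = "pdb"

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coord_array(self) -> np.ndarray:
        atoms = self.atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def get_residue(self, rid: tuple[str, int, str]) -> Optional[Residue]:
        for r in self.residues:
            if r.rid == rid:
                return r
        return None

    def receptor_residues(self) -> list[Residue]:
        """Protein (non-hetero) residues."""
        return [r for r in self.residues if not r.is_hetero]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_hetero]

    def receptor_only(self) -> "Structure":
        return Structure([r.copy() for r in self.receptor_residues()],
                         title=self.title, source_format=self.source_format)

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues],
                         title=self.title, source_format=self.source_format)

    def validate(self) -> None:
        seen_rids: set[tuple[str, int, str]] = set()
        seen_serials: set[int] = set()
        for r in self.residues:
            if r.rid in seen_rids:
                raise ValueError(f"duplicate residue id {format_rid(r.rid)}")
            seen_rids.add(r.rid)
            names: set[str] = set()
            for a in r.atoms:
                if a.serial in seen_serials:
                    raise ValueError(f"duplicate atom serial {a.serial}")
                seen_serials.add(a.serial)
                if a.name in names:
                    raise ValueError(f"duplicate atom name {a.name!r} in {format_rid(r.rid)}")
                names.add(a.name)


@dataclass(frozen=True)
class LigandSelector:
    """Identifies one hetero group: RESNAME:CHAIN:RESSEQ."""

    res_name: str
    chain_id: str
    res_seq: int

    def __str__(self) -> str:
        return f"{self.res_name}:{self.chain_id}:{self.res_seq}"

    @classmethod
    def parse(cls, text: str) -> "LigandSelector":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"ligand selector must be RESNAME:CHAIN:RESSEQ, got {text!r}")
        return cls(parts[0].strip().upper(), parts[1].strip(), int(parts[2]))


@dataclass
class LigandModel:
    """A scoreable ligand: atoms with AD types and partial charges set.

    Bridge waters merged into the ligand PDBQT travel here as ordinary
    ligand atoms, which is how water-mediated contacts enter the score.
    """

    atoms: list[Atom]
    selector: Optional[LigandSelector] = None
    includes_bridge_waters: bool = False

    def validate(self) -> None:
        for a in self.atoms:
            if a.ad_type is None:
                raise ValueError(f"ligand atom {a.serial} {a.name!r} has no AutoDock type")
            if a.partial_charge is None or not np.isfinite(a.partial_charge):
                raise ValueError(f"ligand atom {a.serial} {a.name!r} has no finite partial charge")

    @property
    def total_charge(self) -> float:
        return float(sum(a.partial_charge or 0.0 for a in self.atoms))

    def coord_array(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def copy(self) -> "LigandModel":
        return LigandModel([a.copy() for a in self.atoms], self.selector,
                           self.includes_bridge_waters)
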