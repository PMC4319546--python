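import warnings

import numpy as np
import pytest

from abscan.model import Atom, Residue, Structure
from abscan.synth import ToySpec, ccd_residue_atoms, make_toy_complex


def single_residue_structure(res_name: str) -> Structure:
    """One chemically complete (CCD-capped) residue as a receptor structure."""
    return Structure([Residue("A", 1, res_name, "", ccd_residue_atoms(res_name))])


def molecule_structure(ccd_id: str, res_name: str = None) -> Structure:
    """A CCD small molecule as a single hetero-free residue (for prep tests)."""
    atoms = ccd_residue_atoms(ccd_id)
    return Structure([Residue("A", 1, res_name or ccd_id, "", atoms)])


@pytest.fixture(scope="session")
def toy_complex() -> Structure:
    """Deterministic 8-residue complex, residues 1,2,3,5 in ligand contact."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_toy_complex(ToySpec(n_residues=8, contact_residues=[1, 2, 3, 5], seed=3))


@pytest.fixture(scope="session")
def toy_spec() -> ToySpec:
    return ToySpec(n_residues=8, contact_residues=[1, 2, 3, 5], seed=3)


@pytest.fixture()
def serine() -> Structure:
    return single_residue_structure("SER")


@pytest.fixture()
def phenylalanine() -> Structure:
    return single_residue_structure("PHE")


@pytest.fixture()
def tryptophan() -> Structure:
    return single_residue_structure("TRP")


def methane_structure() -> Structure:
    d = 1.09 / np.sqrt(3.0)
    coords = [(0, 0, 0), (d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
    atoms = [Atom(1, "C1", "C", coords[0])] + [
        Atom(k + 1, f"H{k}", "H", coords[k]) for k in range(1, 5)]
    return Structure([Residue("A", 1, "UNL", "", atoms)])


def random_scoring_atoms(rng: np.random.Generator, n: int, *, hetero: bool,
                         box: float = 12.0, serial_start: int = 1) -> list[Atom]:
    """Random typed/charged atoms inside a cube, for scoring oracles."""
    types = ["C", "A", "N", "NA", "OA", "S", "SA", "HD", "H", "Cl", "P"]
    elements = {"C": "C", "A": "C", "N": "N", "NA": "N", "OA": "O", "S": "S",
                "SA": "S", "HD": "H", "H": "H", "Cl": "Cl", "P": "P"}
    atoms = []
    for k in range(n):
        t = types[rng.integers(len(types))]
        atoms.append(Atom(
            serial=serial_start + k, name=f"X{k}", element=elements[t],
            coords=rng.uniform(-box / 2, box / 2, 3), is_hetero=hetero,
            ad_type=t, partial_charge=float(rng.uniform(-0.5, 0.5))))
    return atoms
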