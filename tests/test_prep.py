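"""Bond inference, AutoDock typing, PEOE charges and hydrogen handling."""

import warnings

import numpy as np
import pytest

from abscan.bonds import infer_bonds
from abscan.model import Atom, Residue, Structure
from abscan.params import SUPPORTED_AD_TYPES
from abscan.prep import (
    assign_autodock_types,
    assign_gasteiger_charges,
    charge_type_table,
    check_hydrogens,
    prepare_receptor,
    unite_nonpolar_hydrogens,
)

from conftest import methane_structure, molecule_structure, single_residue_structure


def _prep(structure):
    bonds = infer_bonds(structure)
    assign_autodock_types(structure, bonds)
    assign_gasteiger_charges(structure, bonds)
    return structure, bonds


def two_carbons(distance: float) -> Structure:
    atoms = [Atom(1, "C1", "C", (0, 0, 0)), Atom(2, "C2", "C", (distance, 0, 0))]
    return Structure([Residue("A", 1, "UNL", "", atoms)])


@pytest.mark.parametrize("distance,bonded", [(1.54, True), (4.0, False)])
def test_carbon_pair_bonding_threshold(distance, bonded):
    assert infer_bonds(two_carbons(distance)).n_bonds == (1 if bonded else 0)


def test_ethanol_has_eight_bonds():
    ethanol = molecule_structure("EOH")  # C2H5OH, 9 atoms
    assert infer_bonds(ethanol).n_bonds == 8


def test_hydrogen_degree_capped_at_one():
    # H placed ambiguously between two carbons still bonds only once
    atoms = [Atom(1, "C1", "C", (0, 0, 0)), Atom(2, "C2", "C", (2.4, 0, 0)),
             Atom(3, "H1", "H", (1.15, 0, 0))]
    bonds = infer_bonds(Structure([Residue("A", 1, "UNL", "", atoms)]))
    assert bonds.degree(2) == 1


def test_serine_hydroxyl_oxygen_typed_as_acceptor(serine):
    s, bonds = _prep(serine)
    assert s.residues[0].atom("OG").ad_type == "OA"


def test_backbone_amide_hydrogen_typed_hd(serine):
    s, _ = _prep(serine)
    assert s.residues[0].atom("H").ad_type == "HD"
    # carbon-bound hydrogens are nonpolar H (pre-merge)
    assert s.residues[0].atom("HA").ad_type == "H"


def test_phenylalanine_ring_carbons_aromatic(phenylalanine):
    s, _ = _prep(phenylalanine)
    res = s.residues[0]
    for name in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"):
        assert res.atom(name).ad_type == "A", name
    assert res.atom("CB").ad_type == "C"  # aliphatic carbon stays C


def test_tryptophan_indole_nitrogen_is_donor_not_acceptor(tryptophan):
    s, _ = _prep(tryptophan)
    assert s.residues[0].atom("NE1").ad_type == "N"


def test_methane_carbon_peoe_charge_matches_published_value():
    s, _ = _prep(methane_structure())
    c = s.residues[0].atom("C1")
    assert c.partial_charge == pytest.approx(-0.078, abs=2e-3)
    assert sum(a.partial_charge for a in s.atoms()) == pytest.approx(0.0, abs=1e-6)


def test_peoe_matches_rdkit_on_ethanol():
    """Independent PEOE oracle: RDKit's Gasteiger implementation."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    AllChem.ComputeGasteigerCharges(mol)
    ref = {"C1": float(mol.GetAtomWithIdx(0).GetProp("_GasteigerCharge")),
           "C2": float(mol.GetAtomWithIdx(1).GetProp("_GasteigerCharge")),
           "O": float(mol.GetAtomWithIdx(2).GetProp("_GasteigerCharge"))}
    s, _ = _prep(molecule_structure("EOH"))
    res = s.residues[0]
    # EOH names: C1 is the carbinol carbon (bonded to O), C2 the methyl
    assert res.atom("C1").partial_charge == pytest.approx(ref["C2"], abs=0.02)
    assert res.atom("C2").partial_charge == pytest.approx(ref["C1"], abs=0.02)
    assert res.atom("O").partial_charge == pytest.approx(ref["O"], abs=0.02)


def test_peoe_charges_invariant_under_atom_reordering(serine):
    s1, _ = _prep(serine.copy())
    shuffled = serine.copy()
    rng = np.random.default_rng(0)
    order = rng.permutation(len(shuffled.residues[0].atoms))
    shuffled.residues[0].atoms = [shuffled.residues[0].atoms[i] for i in order]
    s2, _ = _prep(shuffled)
    for a in s1.residues[0].atoms:
        b = s2.residues[0].atom(a.name)
        assert b.partial_charge == pytest.approx(a.partial_charge, abs=1e-9)
        assert b.ad_type == a.ad_type


def test_charge_seeding_gives_ionized_side_chains():
    lys, _ = _prep(single_residue_structure("LYS"))  # NZ carries 3 H in the CCD
    assert sum(a.partial_charge for a in lys.atoms()) == pytest.approx(1.0, abs=1e-6)
    asp, _ = _prep(single_residue_structure("ASP"))  # neutral acid (has HD2)
    assert sum(a.partial_charge for a in asp.atoms()) == pytest.approx(0.0, abs=1e-6)


def test_unite_methane_collapses_to_neutral_united_carbon():
    s, bonds = _prep(methane_structure())
    united = unite_nonpolar_hydrogens(s, bonds)
    assert united.n_atoms == 1
    assert united.atoms()[0].partial_charge == pytest.approx(0.0, abs=1e-12)


def test_unite_keeps_polar_hydrogens_and_conserves_charge(serine):
    s, bonds = _prep(serine)
    before = sum(a.partial_charge for a in s.atoms())
    united = unite_nonpolar_hydrogens(s, bonds)
    after = sum(a.partial_charge for a in united.atoms())
    assert after == pytest.approx(before, abs=1e-12)
    names = {a.name for a in united.atoms()}
    assert "HG" in names and "H" in names  # O-H and N-H survive
    assert not any(n.startswith("HB") for n in names)  # C-H merged


def test_check_hydrogens_places_serine_hg_at_ideal_length(serine):
    bare = serine.copy()
    res = bare.residues[0]
    res.atoms = [a for a in res.atoms if a.name != "HG"]
    completed = check_hydrogens(bare)
    hg = completed.residues[0].atom("HG")
    og = completed.residues[0].atom("OG")
    assert hg is not None
    assert np.linalg.norm(hg.coords - og.coords) == pytest.approx(0.96, abs=1e-6)


def test_check_hydrogens_is_idempotent(serine):
    once = check_hydrogens(serine)
    twice = check_hydrogens(once)
    assert twice.n_atoms == once.n_atoms == serine.n_atoms


def test_check_hydrogens_leaves_nonstandard_residues_untouched():
    lig = molecule_structure("IPA", res_name="IPA")
    with pytest.warns(UserWarning, match="nonstandard"):
        out = check_hydrogens(lig)
    assert out.n_atoms == lig.n_atoms


def test_added_hydrogen_is_typed_and_charged_by_the_pipeline(serine):
    bare = serine.copy()
    res = bare.residues[0]
    res.atoms = [a for a in res.atoms if a.name != "HG"]
    prepared = prepare_receptor(bare)
    hg = prepared.residues[0].atom("HG")
    assert hg.ad_type == "HD"
    assert hg.partial_charge is not None and hg.partial_charge > 0.1


def test_prepared_receptor_types_all_supported_and_charge_conserved(toy_complex):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepared = prepare_receptor(toy_complex.receptor_only())
    assert {a.ad_type for a in prepared.atoms()} <= SUPPORTED_AD_TYPES
    # toy has one CCD LYS (+1); everything else is neutral
    total = sum(a.partial_charge for a in prepared.atoms())
    assert total == pytest.approx(round(total), abs=1e-6)
    table = charge_type_table(prepared)
    assert table.count("\n") == prepared.n_atoms + 1
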