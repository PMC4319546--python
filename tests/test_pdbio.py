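"""PDB/PDBQT parsing and writing: transcription, alt-locs, round-trips."""

import io
import warnings

import numpy as np
import pytest

from abscan.mutate import mutate_to_alanine
from abscan.pdbio import PDBFormatWarning, PDBParseError, parse_pdb, parse_pdbqt, write_pdb

TWO_ATOMS = """\
ATOM      1  N   SER A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   2      12.560   6.071  -6.342  1.00  0.00           C
"""

ALTLOC = """\
ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BSER A   1       1.000   0.000   0.000  0.40  0.00           C
"""

PDBQT_3ATOM = """\
REMARK  3-atom probe
ROOT
ATOM      1  O   LIG L   1       0.000   0.000   0.000  1.00  0.00    -0.360 OA
ATOM      2  H1  LIG L   1       0.960   0.000   0.000  1.00  0.00     0.180 HD
ATOM      3  H2  LIG L   1      -0.240   0.930   0.000  1.00  0.00     0.180 HD
ENDROOT
TORSDOF 0
"""


def test_two_atom_lines_transcribed_directly():
    s = parse_pdb(TWO_ATOMS)
    assert s.n_atoms == 2
    assert [r.res_name for r in s.residues] == ["SER", "GLY"]
    a = s.residues[0].atoms[0]
    assert (a.name, a.element) == ("N", "N")
    np.testing.assert_allclose(a.coords, [11.104, 6.134, -6.504])


def test_altloc_keeps_highest_occupancy():
    s = parse_pdb(ALTLOC)
    assert s.n_atoms == 1
    assert s.atoms()[0].alt_loc == "A"
    assert s.atoms()[0].coords[0] == 0.0


def test_altloc_tie_breaks_alphabetically():
    tie = ALTLOC.replace("0.60", "0.40")
    s = parse_pdb(tie)
    assert s.n_atoms == 1
    assert s.atoms()[0].alt_loc == "A"


def test_no_coordinate_records_is_an_error():
    with pytest.raises(PDBParseError):
        parse_pdb("HEADER    EMPTY\nEND\n")


def test_malformed_record_skipped_with_line_number():
    bad = TWO_ATOMS + "ATOM      3  CB  SER A   1      bad-x   0.000   0.000\n"
    with pytest.warns(PDBFormatWarning, match="line 3"):
        s = parse_pdb(bad)
    assert s.n_atoms == 2


def test_parsing_ignores_ter_anisou_conect_and_trailing_whitespace():
    decorated = (
        TWO_ATOMS.rstrip("\n").replace("\n", "   \n") + "   \n"
        + "ANISOU    1  N   SER A   1     1000   1000   1000      0      0      0\n"
        + "TER       3      GLY A   2\nCONECT    1    2\nEND\n")
    s = parse_pdb(decorated)
    assert s.n_atoms == 2


def test_multi_model_keeps_first_with_warning():
    multi = ("MODEL        1\n" + TWO_ATOMS + "ENDMDL\n"
             + "MODEL        2\n" + TWO_ATOMS + "ENDMDL\n")
    with pytest.warns(PDBFormatWarning, match="first model"):
        s = parse_pdb(multi)
    assert s.n_atoms == 2


def test_pdbqt_charges_taken_verbatim():
    lig = parse_pdbqt(PDBQT_3ATOM)
    assert [a.partial_charge for a in lig.atoms] == [-0.36, 0.18, 0.18]
    assert lig.total_charge == pytest.approx(0.0, abs=1e-12)
    assert [a.ad_type for a in lig.atoms] == ["OA", "HD", "HD"]


def test_pdbqt_branch_records_do_not_change_atoms():
    branched = PDBQT_3ATOM.replace("ENDROOT", "ENDROOT\nBRANCH   1   2\nENDBRANCH   1   2")
    assert [a.serial for a in parse_pdbqt(branched).atoms] == \
        [a.serial for a in parse_pdbqt(PDBQT_3ATOM).atoms]


def test_pdbqt_waters_flag_bridge_waters_and_score_as_ligand():
    with_waters = PDBQT_3ATOM.replace("TORSDOF 0", "") + (
        "ATOM      4  O   HOH L   2       3.000   0.000   0.000  1.00  0.00"
        "    -0.411 OA\n"
        "ATOM      5  H1  HOH L   2       3.960   0.000   0.000  1.00  0.00"
        "     0.205 HD\n")
    lig = parse_pdbqt(with_waters)
    assert lig.includes_bridge_waters
    assert len(lig.atoms) == 5  # waters are ordinary ligand atoms


def test_pdbqt_missing_charge_columns_is_a_format_error():
    truncated = "ATOM      1  O   LIG L   1       0.000   0.000   0.000  1.00  0.00\n"
    with pytest.raises(PDBParseError, match="line 1"):
        parse_pdbqt(truncated)


def test_roundtrip_preserves_inventory_and_coordinates(toy_complex):
    text = write_pdb(toy_complex)
    back = parse_pdb(text)
    assert back.n_atoms == toy_complex.n_atoms
    for r1, r2 in zip(toy_complex.residues, back.residues):
        assert r1.rid == r2.rid and r1.res_name == r2.res_name
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        assert [a.element for a in r1.atoms] == [a.element for a in r2.atoms]
        np.testing.assert_allclose(r1.coord_array(), r2.coord_array(), atol=5e-4)


def test_double_roundtrip_is_identity(toy_complex):
    once = write_pdb(parse_pdb(write_pdb(toy_complex)))
    assert once == write_pdb(parse_pdb(once))


def test_mutant_written_with_ala_residue_name(toy_complex):
    rid = ("A", 3, "")  # TRP in the default residue cycle
    mutant = mutate_to_alanine(toy_complex.receptor_only(), rid)
    text = write_pdb(mutant.structure)
    back = parse_pdb(text)
    assert back.get_residue(rid).res_name == "ALA"


def test_biopython_agrees_on_atom_inventory(toy_complex):
    """Independent reader cross-check: same atoms, same coordinates."""
    from Bio.PDB import PDBParser

    text = write_pdb(toy_complex)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = PDBParser(QUIET=True).get_structure("toy", io.StringIO(text))
    bio_atoms = list(bio.get_atoms())
    assert len(bio_atoms) == toy_complex.n_atoms
    ours = np.array([a.coords for a in toy_complex.atoms()])
    theirs = np.array([a.get_coord() for a in bio_atoms])
    np.testing.assert_allclose(
        np.sort(ours.round(3), axis=0), np.sort(theirs, axis=0), atol=5e-4)
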