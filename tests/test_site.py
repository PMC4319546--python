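"""Ligand candidates and binding-site selection under the distance cutoff."""

import inspect

import numpy as np
import pytest

from abscan.model import Atom, LigandSelector, Residue, Structure
from abscan.site import (
    NoLigandError,
    list_ligand_candidates,
    select_binding_site,
)
from abscan.synth import ccd_residue_atoms


def _point_residue(seq, x, element="C", hetero=False, res_name=None):
    name = res_name or ("LIG" if hetero else "GLY")
    return Residue("A" if not hetero else "L", seq, name, "",
                   [Atom(serial=seq * 10, name=element.upper(), element=element,
                         coords=(x, 0.0, 0.0), is_hetero=hetero)])


def test_boundary_inclusion_at_the_cutoff():
    lig = _point_residue(1, 0.0, hetero=True, res_name="LIG")
    lig.atoms.append(Atom(serial=11, name="C2", element="C", coords=(0.5, 0, 0),
                          is_hetero=True))
    near = _point_residue(2, 4.4 + 0.5)
    far = _point_residue(3, 4.6 + 0.5)
    s = Structure([near, far, lig])
    site = select_binding_site(s, LigandSelector("LIG", "L", 1))
    assert [m.rid for m in site.residues] == [("A", 2, "")]
    assert site.residues[0].min_distance == pytest.approx(4.4)


def test_default_cutoff_is_4_5_angstrom():
    assert inspect.signature(select_binding_site).parameters["cutoff"].default == 4.5


def test_waters_and_ions_are_not_ligand_candidates():
    drug = Residue("L", 1, "DRG", "", [
        Atom(serial=100 + k, name=f"C{k}", element="C", coords=(k, 0, 0),
             is_hetero=True) for k in range(5)])
    waters = [Residue("W", 10 + k, "HOH", "", [
        Atom(serial=200 + k, name="O", element="O", coords=(0, k, 0), is_hetero=True)])
        for k in range(50)]
    ion = Residue("I", 99, "ZN", "", [
        Atom(serial=900, name="ZN", element="Zn", coords=(9, 9, 9), is_hetero=True)])
    s = Structure([_point_residue(1, 20.0), drug, ion] + waters)
    assert list_ligand_candidates(s) == [LigandSelector("DRG", "L", 1)]


def test_candidates_ordered_by_heavy_atom_count():
    """Cofactor vs steroid: NADP (48 heavy atoms) outranks testosterone (21)."""
    tes = Residue("A", 500, "TES", "", ccd_residue_atoms("TES", 1000))
    nap = Residue("A", 600, "NAP", "", ccd_residue_atoms("NAP", 2000))
    for r in (tes, nap):
        for a in r.atoms:
            a.is_hetero = True
    for a in nap.atoms:  # keep the two groups spatially apart
        a.coords = a.coords + np.array([40.0, 0.0, 0.0])
    s = Structure([_point_residue(1, -20.0), tes, nap])
    sels = list_ligand_candidates(s)
    assert [x.res_name for x in sels] == ["NAP", "TES"]


def test_apo_structure_raises_no_ligand_error():
    s = Structure([_point_residue(i, float(i)) for i in range(1, 4)])
    with pytest.raises(NoLigandError):
        list_ligand_candidates(s)


def test_empty_site_warns_but_is_not_an_error():
    lig = _point_residue(1, 100.0, hetero=True, res_name="LIG")
    lig.atoms.append(Atom(serial=12, name="C2", element="C", coords=(101, 0, 0),
                          is_hetero=True))
    s = Structure([_point_residue(2, 0.0), lig])
    with pytest.warns(UserWarning, match="no receptor residue"):
        site = select_binding_site(s, LigandSelector("LIG", "L", 1))
    assert len(site) == 0


def _random_structure(seed, n_res=50):
    rng = np.random.default_rng(seed)
    residues = []
    serial = 1
    for i in range(1, n_res + 1):
        center = rng.uniform(-15, 15, 3)
        atoms = []
        for k in range(rng.integers(3, 9)):
            atoms.append(Atom(serial=serial, name=f"C{k}", element="C",
                              coords=center + rng.uniform(-1.5, 1.5, 3)))
            serial += 1
        residues.append(Residue("A", i, "GLY", "", atoms))
    lig = Residue("L", 1, "LIG", "", [
        Atom(serial=9000 + k, name=f"C{k}", element="C",
             coords=rng.uniform(-4, 4, 3), is_hetero=True) for k in range(8)])
    return Structure(residues + [lig])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_site_agrees_with_brute_force_double_loop(seed):
    s = _random_structure(seed)
    site = select_binding_site(s, LigandSelector("LIG", "L", 1), cutoff=4.5)
    lig_coords = s.get_residue(("L", 1, "")).coord_array()
    expected = []
    for res in s.residues:
        if res.is_hetero:
            continue
        dmin = min(np.linalg.norm(a.coords - lc)
                   for a in res.atoms for lc in lig_coords)
        if dmin <= 4.5:
            expected.append(res.rid)
    assert site.rids() == sorted(expected)


def test_site_is_monotone_in_cutoff():
    s = _random_structure(5)
    sel = LigandSelector("LIG", "L", 1)
    previous = set()
    for cutoff in (2.0, 3.5, 4.5, 6.0, 9.0):
        current = set(select_binding_site(s, sel, cutoff=cutoff).rids())
        assert previous <= current
        previous = current


def test_contact_atom_count_and_sorted_order(toy_complex):
    site = select_binding_site(toy_complex, LigandSelector("IPA", "L", 1))
    assert site.rids() == sorted(site.rids())
    for m in site.residues:
        assert m.n_contact_atoms >= 1
        assert m.min_distance <= site.cutoff
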