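"""Closed-form oracles and structural properties of the pairwise score."""

import math

import numpy as np
import pytest

from abscan.model import LigandModel, Residue, Structure
from abscan.params import AD4_ATOM_PARAMS, DEFAULT_SCORING, combine_lj
from abscan.scoring import (
    EnergyBreakdown,
    desolv_energy,
    elec_energy,
    hbond_energy,
    interaction_energy,
    pair_energy,
    vdw_energy,
)

from conftest import random_scoring_atoms

P = DEFAULT_SCORING


@pytest.mark.parametrize("pair", [("C", "C"), ("C", "OA"), ("N", "SA"), ("A", "HD")])
def test_vdw_minimum_is_minus_eps_at_rij(pair):
    r_min, eps = combine_lj(*pair)
    assert vdw_energy(r_min, *pair) == pytest.approx(-eps, rel=1e-12)


def test_vdw_at_twice_rij_matches_hand_evaluated_12_6():
    r_min, eps = combine_lj("C", "C")
    r = 2.0 * r_min
    rs = r - 0.5 * P.smoothing_width  # smoothing pulls r toward the minimum
    expected = eps * r_min**12 / rs**12 - 2.0 * eps * r_min**6 / rs**6
    assert vdw_energy(r, "C", "C") == pytest.approx(expected, rel=1e-12)


def test_vdw_clamped_at_ceiling_for_tiny_r():
    assert vdw_energy(0.1, "C", "C") == P.energy_ceiling


def test_hbond_minimum_is_minus_five_kcal_at_1_9_angstrom():
    assert hbond_energy(1.9, "HD", "OA") == pytest.approx(-5.0, rel=1e-12)
    assert hbond_energy(1.9, "NA", "HD") == pytest.approx(-5.0, rel=1e-12)


def test_hbond_sulfur_acceptor_uses_its_own_well():
    assert hbond_energy(2.5, "HD", "SA") == pytest.approx(-1.0, rel=1e-12)


def test_hbond_zero_for_non_hbonding_pairs():
    for r in (1.9, 3.0, 5.0):
        assert hbond_energy(r, "C", "C") == 0.0
        assert hbond_energy(r, "OA", "OA") == 0.0  # two acceptors, no donor


def test_elec_zero_charge_gives_zero():
    for r in (1.0, 3.0, 7.9):
        assert elec_energy(r, 0.0, 0.3) == 0.0


def test_elec_antisymmetry_in_charge_sign():
    assert elec_energy(5.0, 1.0, -1.0) == -elec_energy(5.0, 1.0, 1.0)


def test_elec_matches_hand_evaluated_mehler_solmajer():
    # independent transcription of the sigmoidal dielectric
    A, eps0, lam, k = -8.5525, 78.4, 0.003627, 7.7839
    B = eps0 - A
    r = 5.0
    eps_r = A + B / (1.0 + k * math.exp(-lam * B * r))
    expected = 332.06363 * 1.0 * 1.0 / (eps_r * r)
    assert elec_energy(r, 1.0, 1.0) == pytest.approx(expected, rel=1e-12)


def test_desolv_gaussian_decay_ratio_at_sigma():
    near = desolv_energy(1e-9, "C", "C", 0.0, 0.0)
    at_sigma = desolv_energy(P.desolv_sigma, "C", "C", 0.0, 0.0)
    assert at_sigma / near == pytest.approx(math.exp(-0.5), rel=1e-9)


def test_desolv_matches_hand_evaluation_from_parameter_table():
    p = AD4_ATOM_PARAMS["C"]
    r = 3.6
    expected = 2.0 * p.solpar * p.vol * math.exp(-r * r / (2.0 * P.desolv_sigma**2))
    assert desolv_energy(r, "C", "C", 0.0, 0.0) == pytest.approx(expected, rel=1e-12)
    # charge-dependent solvation term raises |S|
    q = 0.4
    s_q = p.solpar + P.qsolpar * q
    expected_q = 2.0 * s_q * p.vol * math.exp(-r * r / (2.0 * P.desolv_sigma**2))
    assert desolv_energy(r, "C", "C", q, -q) == pytest.approx(expected_q, rel=1e-12)


@pytest.mark.parametrize("term", [
    lambda r: vdw_energy(r, "C", "C"),
    lambda r: hbond_energy(r, "HD", "OA"),
    lambda r: elec_energy(r, 0.5, -0.5),
    lambda r: desolv_energy(r, "C", "OA", 0.2, -0.1),
])
def test_every_term_is_exactly_zero_beyond_the_cutoff(term):
    assert term(P.nb_cutoff + 1e-9) == 0.0
    assert term(20.0) == 0.0


def test_pair_energy_components_sum_to_total():
    e = pair_energy(3.0, "OA", "HD", -0.4, 0.3)
    assert e.total == pytest.approx(e.vdw + e.hbond + e.elec + e.desolv, abs=1e-15)


def test_unknown_type_fails_loudly():
    with pytest.raises(KeyError, match="Fe"):
        pair_energy(3.0, "Fe", "C", 0.0, 0.0)


def _random_system(seed, n_rec=60, n_lig=40):
    rng = np.random.default_rng(seed)
    rec_atoms = random_scoring_atoms(rng, n_rec, hetero=False)
    lig_atoms = random_scoring_atoms(rng, n_lig, hetero=True, serial_start=1000)
    receptor = Structure([Residue("A", 1, "UNK", "", rec_atoms)])
    ligand = LigandModel(lig_atoms)
    return receptor, ligand


def _brute_force(receptor, ligand):
    total = EnergyBreakdown()
    for ra in receptor.atoms():
        for la in ligand.atoms:
            r = float(np.linalg.norm(ra.coords - la.coords))
            if r <= P.nb_cutoff:
                total = total + pair_energy(r, ra.ad_type, la.ad_type,
                                            ra.partial_charge, la.partial_charge)
    return total


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_interaction_energy_equals_all_pairs_double_loop(seed):
    receptor, ligand = _random_system(seed)
    fast = interaction_energy(receptor, ligand)
    slow = _brute_force(receptor, ligand)
    for k in ("vdw", "hbond", "elec", "desolv", "total"):
        assert fast.as_dict()[k] == pytest.approx(slow.as_dict()[k], abs=1e-9)


def test_pairwise_additivity_over_disjoint_receptor_subsets():
    receptor, ligand = _random_system(7)
    atoms = receptor.atoms()
    ra = Structure([Residue("A", 1, "UNK", "", [a.copy() for a in atoms[:30]])])
    rb = Structure([Residue("A", 2, "UNK", "", [a.copy() for a in atoms[30:]])])
    whole = interaction_energy(receptor, ligand).total
    split = interaction_energy(ra, ligand).total + interaction_energy(rb, ligand).total
    assert split == pytest.approx(whole, abs=1e-9)


def test_receptor_ligand_role_symmetry():
    receptor, ligand = _random_system(11)
    swapped_receptor = Structure([Residue("A", 1, "UNK", "",
                                          [a.copy() for a in ligand.atoms])])
    swapped_ligand = LigandModel([a.copy() for a in receptor.atoms()])
    e1 = interaction_energy(receptor, ligand).total
    e2 = interaction_energy(swapped_receptor, swapped_ligand).total
    assert e2 == pytest.approx(e1, abs=1e-9)


def test_empty_ligand_scores_zero():
    receptor, _ = _random_system(0)
    e = interaction_energy(receptor, LigandModel([]))
    assert e.total == 0.0 and e.vdw == 0.0


def test_ligand_translated_beyond_cutoff_scores_exactly_zero():
    receptor, ligand = _random_system(3)
    far = ligand.copy()
    for a in far.atoms:
        a.coords = a.coords + np.array([100.0, 0.0, 0.0])
    assert interaction_energy(receptor, far).total == 0.0
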