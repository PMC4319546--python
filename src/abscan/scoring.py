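"""Pairwise semi-empirical interaction energy (AutoDock4-style).

Four weighted terms summed over receptor-ligand atom pairs within the
non-bonded cutoff, for a fixed pose (no docking, no intramolecular or
torsional contributions — those cancel in the mutant-minus-wild-type
difference the scan reports):

  vdW      W_vdw  * (A_ij/r^12 - B_ij/r^6)         Lennard-Jones 12-6
  H-bond   W_hb   * (C_ij/r^12 - D_ij/r^10)        12-10, polar-H/acceptor pairs
  elec     W_elec * 332.06363 q_i q_j / (eps(r) r)  Mehler-Solmajer dielectric
  desolv   W_sol  * (S_i V_j + S_j V_i) exp(-r^2/(2 sigma^2))

The 12-6 and 12-10 terms use AutoDock's distance smoothing: the pair
distance is moved toward the pair minimum by up to half the smoothing
width before evaluation. The hydrogen-bond term is distance-only (no
angular ramp); see the methods note for why this is adequate for
rescoring a fixed pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import LigandModel, Structure
from .params import (
    AD4_ATOM_PARAMS,
    DEFAULT_SCORING,
    ScoringParams,
    combine_lj,
    hbond_pair,
)

__all__ = ["EnergyBreakdown", "vdw_energy", "hbond_energy", "elec_energy",
           "desolv_energy", "pair_energy", "interaction_energy"]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Post-weighting intermolecular energy components, kcal/mol."""

    vdw: float = 0.0
    hbond: float = 0.0
    elec: float = 0.0
    desolv: float = 0.0

    @property
    def total(self) -> float:
        return self.vdw + self.hbond + self.elec + self.desolv

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.vdw + other.vdw, self.hbond + other.hbond,
                               self.elec + other.elec, self.desolv + other.desolv)

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.vdw - other.vdw, self.hbond - other.hbond,
                               self.elec - other.elec, self.desolv - other.desolv)

    def as_dict(self) -> dict[str, float]:
        return {"vdw": self.vdw, "hbond": self.hbond, "elec": self.elec,
                "desolv": self.desolv, "total": self.total}


def _smooth(r: float, r_min: float, width: float) -> float:
    """Move r toward the pair minimum by up to width/2 (AutoDock smoothing)."""
    half = 0.5 * width
    if r > r_min + half:
        return r - half
    if r < r_min - half:
        return r + half
    return r_min


def vdw_energy(r: float, type_i: str, type_j: str,
               params: ScoringParams = DEFAULT_SCORING) -> float:
    """Unweighted 12-6 dispersion/repulsion energy for one pair, kcal/mol."""
    if r > params.nb_cutoff:
        return 0.0
    r_min, eps = combine_lj(type_i, type_j)
    rs = _smooth(r, r_min, params.smoothing_width)
    a = eps * r_min ** 12
    b = 2.0 * eps * r_min ** 6
    e = a / rs ** 12 - b / rs ** 6
    return min(e, params.energy_ceiling)


def hbond_energy(r: float, type_i: str, type_j: str,
                 params: ScoringParams = DEFAULT_SCORING) -> float:
    """Unweighted 12-10 hydrogen-bond energy; zero unless the pair is a
    polar hydrogen with an O/N/S acceptor."""
    if r > params.nb_cutoff:
        return 0.0
    hb = hbond_pair(type_i, type_j)
    if hb is None:
        return 0.0
    r_hb, eps_hb = hb
    rs = _smooth(r, r_hb, params.smoothing_width)
    c = 5.0 * eps_hb * r_hb ** 12
    d = 6.0 * eps_hb * r_hb ** 10
    e = c / rs ** 12 - d / rs ** 10
    return min(e, params.energy_ceiling)


def elec_energy(r: float, q_i: float, q_j: float,
                params: ScoringParams = DEFAULT_SCORING) -> float:
    """Unweighted screened Coulomb energy with the sigmoidal
    distance-dependent dielectric of Mehler & Solmajer."""
    if r > params.nb_cutoff or r <= 0.0:
        return 0.0
    e = params.coulomb_constant * q_i * q_j / (params.dielectric(r) * r)
    return min(e, params.energy_ceiling)


def desolv_energy(r: float, type_i: str, type_j: str, q_i: float, q_j: float,
                  params: ScoringParams = DEFAULT_SCORING) -> float:
    """Unweighted Gaussian-attenuated pairwise desolvation energy."""
    if r > params.nb_cutoff:
        return 0.0
    pi, pj = AD4_ATOM_PARAMS[type_i], AD4_ATOM_PARAMS[type_j]
    s_i = pi.solpar + params.qsolpar * abs(q_i)
    s_j = pj.solpar + params.qsolpar * abs(q_j)
    return (s_i * pj.vol + s_j * pi.vol) * math.exp(-r * r / (2.0 * params.desolv_sigma ** 2))


def pair_energy(r: float, type_i: str, type_j: str, q_i: float, q_j: float,
                params: ScoringParams = DEFAULT_SCORING) -> EnergyBreakdown:
    """Weighted per-pair breakdown; components sum to the pair total."""
    if type_i not in AD4_ATOM_PARAMS:
        raise KeyError(f"no force-field parameters for AutoDock type {type_i!r}")
    if type_j not in AD4_ATOM_PARAMS:
        raise KeyError(f"no force-field parameters for AutoDock type {type_j!r}")
    return EnergyBreakdown(
        vdw=params.W_vdw * vdw_energy(r, type_i, type_j, params),
        hbond=params.W_hb * hbond_energy(r, type_i, type_j, params),
        elec=params.W_elec * elec_energy(r, q_i, q_j, params),
        desolv=params.W_sol * desolv_energy(r, type_i, type_j, q_i, q_j, params),
    )


def _scoring_arrays(atoms) -> tuple[np.ndarray, list[str], np.ndarray]:
    coords = np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)
    types: list[str] = []
    charges = np.zeros(len(atoms))
    for k, a in enumerate(atoms):
        if a.ad_type is None:
            raise ValueError(f"atom {a.serial} {a.name!r} has no AutoDock type")
        if a.partial_charge is None:
            raise ValueError(f"atom {a.serial} {a.name!r} has no partial charge")
        if a.ad_type not in AD4_ATOM_PARAMS:
            raise ValueError(
                f"atom {a.serial} {a.name!r}: AutoDock type {a.ad_type!r} has no "
                f"force-field parameters (supply a ligand PDBQT with supported types)")
        types.append(a.ad_type)
        charges[k] = a.partial_charge
    return coords, types, charges


def interaction_energy(receptor: Structure, ligand: LigandModel,
                       params: ScoringParams = DEFAULT_SCORING) -> EnergyBreakdown:
    """Total intermolecular energy of a fixed receptor-ligand pose.

    Sums the four weighted pair terms over all receptor-ligand atom pairs
    within ``params.nb_cutoff``; a neighbor search keeps it near-linear in
    system size, and the result matches the all-pairs double loop exactly.
    """
    rec_atoms = receptor.atoms()
    lig_atoms = ligand.atoms
    if not rec_atoms or not lig_atoms:
        return EnergyBreakdown()
    rc, rtypes, rq_arr = _scoring_arrays(rec_atoms)
    lc, ltypes, lq_arr = _scoring_arrays(lig_atoms)
    rq = [float(x) for x in rq_arr]
    lq = [float(x) for x in lq_arr]

    tree = cKDTree(lc)
    total = EnergyBreakdown()
    for i, neighbors in enumerate(tree.query_ball_point(rc, params.nb_cutoff)):
        for j in neighbors:
            r = float(np.linalg.norm(rc[i] - lc[j]))
            total = total + pair_energy(r, rtypes[i], ltypes[j], rq[i], lq[j], params)
    return total
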