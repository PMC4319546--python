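"""Force-field and chemistry parameter tables.

All scoring parameters follow the AutoDock 4.1 bound-state set: per-type
Lennard-Jones radii/well depths, atomic fragmental volumes and solvation
parameters, 12-10 hydrogen-bond parameters, and the four linear free-energy
weights. Combination rules are arithmetic for radii (Rij = (Rii+Rjj)/2) and
geometric for well depths (eps_ij = sqrt(eps_ii*eps_jj)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# hydrogen-bond classes
HB_NONE = "none"
HB_DONOR_H = "donor-H"
HB_ACC_O = "acceptor-O"
HB_ACC_N = "acceptor-N"
HB_ACC_S = "acceptor-S"


@dataclass(frozen=True)
class AtomTypeParams:
    ad_type: str
    Rii: float        # Angstrom, vdW distance at the pair minimum (i==j)
    eps_ii: float     # kcal/mol, well depth
    vol: float        # A^3, atomic fragmental solvation volume V_i
    solpar: float     # kcal/(mol*A^3), atomic solvation parameter S_i
    hbond_class: str = HB_NONE
    Rij_hb: float = 0.0    # Angstrom, 12-10 minimum position (acceptor rows)
    eps_ij_hb: float = 0.0  # kcal/mol, 12-10 well depth (acceptor rows)


# AutoDock 4.1 bound-state atom parameters.
AD4_ATOM_PARAMS: dict[str, AtomTypeParams] = {
    p.ad_type: p
    for p in [
        AtomTypeParams("H", 2.00, 0.020, 0.0000, 0.00051),
        AtomTypeParams("HD", 2.00, 0.020, 0.0000, 0.00051, HB_DONOR_H),
        AtomTypeParams("C", 4.00, 0.150, 33.5103, -0.00143),
        AtomTypeParams("A", 4.00, 0.150, 33.5103, -0.00052),
        AtomTypeParams("N", 3.50, 0.160, 22.4493, -0.00162),
        AtomTypeParams("NA", 3.50, 0.160, 22.4493, -0.00162, HB_ACC_N, 1.9, 5.0),
        AtomTypeParams("OA", 3.20, 0.200, 17.1573, -0.00251, HB_ACC_O, 1.9, 5.0),
        AtomTypeParams("SA", 4.00, 0.200, 33.5103, -0.00214, HB_ACC_S, 2.5, 1.0),
        AtomTypeParams("S", 4.00, 0.200, 33.5103, -0.00214),
        AtomTypeParams("F", 3.09, 0.080, 15.4480, -0.00110),
        AtomTypeParams("Cl", 4.09, 0.276, 35.8235, -0.00110),
        AtomTypeParams("Br", 4.33, 0.389, 42.5661, -0.00110),
        AtomTypeParams("I", 4.72, 0.550, 55.0585, -0.00110),
        AtomTypeParams("P", 4.20, 0.200, 38.7924, -0.00110),
    ]
}

SUPPORTED_AD_TYPES = frozenset(AD4_ATOM_PARAMS)


@dataclass(frozen=True)
class ScoringParams:
    """Weights and global constants of the pairwise scoring function."""

    W_vdw: float = 0.1662
    W_hb: float = 0.1209
    W_elec: float = 0.1406
    W_sol: float = 0.1322
    nb_cutoff: float = 8.0          # Angstrom, non-bonded cutoff
    smoothing_width: float = 0.5    # Angstrom, LJ/HB distance smoothing
    desolv_sigma: float = 3.6       # Angstrom, Gaussian desolvation width
    qsolpar: float = 0.01097        # charge-dependent solvation increment
    coulomb_constant: float = 332.06363  # kcal*A/(mol*e^2)
    energy_ceiling: float = 100.0   # kcal/mol clamp per pair term at tiny r
    # Mehler-Solmajer sigmoidal distance-dependent dielectric
    ms_A: float = -8.5525
    ms_eps0: float = 78.4
    ms_lambda: float = 0.003627
    ms_k: float = 7.7839

    @property
    def ms_B(self) -> float:
        return self.ms_eps0 - self.ms_A

    def dielectric(self, r: float) -> float:
        B = self.ms_B
        return self.ms_A + B / (1.0 + self.ms_k * math.exp(-self.ms_lambda * B * r))


DEFAULT_SCORING = ScoringParams()

# ---------------------------------------------------------------------------
# Elemental chemistry tables

COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20, "B": 0.84,
}
DEFAULT_COVALENT_RADIUS = 0.77
BOND_TOLERANCE = 0.45  # Angstrom added to covalent-radius sum

# van der Waals radii for the steric-clash metric (Bondi-style)
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70
CLASH_FACTOR = 0.6  # clash iff d < CLASH_FACTOR * (vdW radius sum), non-bonded

# PEOE (Gasteiger-Marsili) electronegativity coefficients chi = a + b*q + c*q^2,
# keyed by (element, hybridization); None matches any hybridization.
PEOE_COEFFS: dict[tuple[str, str | None], tuple[float, float, float]] = {
    ("H", None): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", None): (14.66, 13.85, 2.31),
    ("CL", None): (11.00, 9.69, 1.35),
    ("BR", None): (10.08, 8.47, 1.16),
    ("I", None): (9.90, 7.96, 0.96),
    ("S", None): (10.14, 9.13, 1.38),
    ("P", None): (8.90, 8.24, 0.96),
}
PEOE_H_CATION_CHI = 20.02  # special cation electronegativity for hydrogen
PEOE_ITERATIONS = 8
PEOE_DAMPING = 0.5

# ---------------------------------------------------------------------------
# Amino-acid topology

# side-chain heavy atoms beyond CB, deleted on mutation to alanine
SIDE_CHAIN_BEYOND_CB: dict[str, frozenset[str]] = {
    "ARG": frozenset("CG CD NE CZ NH1 NH2".split()),
    "ASN": frozenset("CG OD1 ND2".split()),
    "ASP": frozenset("CG OD1 OD2".split()),
    "CYS": frozenset("SG".split()),
    "GLN": frozenset("CG CD OE1 NE2".split()),
    "GLU": frozenset("CG CD OE1 OE2".split()),
    "HIS": frozenset("CG ND1 CD2 CE1 NE2".split()),
    "ILE": frozenset("CG1 CG2 CD1".split()),
    "LEU": frozenset("CG CD1 CD2".split()),
    "LYS": frozenset("CG CD CE NZ".split()),
    "MET": frozenset("CG SD CE".split()),
    "PHE": frozenset("CG CD1 CD2 CE1 CE2 CZ".split()),
    "PRO": frozenset("CG CD".split()),
    "SER": frozenset("OG".split()),
    "THR": frozenset("OG1 CG2".split()),
    "TRP": frozenset("CG CD1 CD2 NE1 CE2 CE3 CZ2 CZ3 CH2".split()),
    "TYR": frozenset("CG CD1 CD2 CE1 CE2 CZ OH".split()),
    "VAL": frozenset("CG1 CG2".split()),
}

# hydrogen names that belong to the alanine/backbone inventory and survive
# side-chain truncation
BACKBONE_H_NAMES = frozenset("H H1 H2 H3 HA HA2 HA3 HXT HN".split())

ALA_ALLOWED_ATOMS = frozenset(
    "N CA C O CB OXT".split()) | BACKBONE_H_NAMES | frozenset("HB1 HB2 HB3".split())

# polar hydrogens expected on standard residues: res_name -> [(H name, parent heavy atom)]
# Backbone amide H is handled separately (every non-PRO residue).
SIDECHAIN_POLAR_H: dict[str, list[tuple[str, str]]] = {
    "SER": [("HG", "OG")],
    "THR": [("HG1", "OG1")],
    "TYR": [("HH", "OH")],
    "CYS": [("HG", "SG")],
    "TRP": [("HE1", "NE1")],
    "HIS": [("HE2", "NE2")],  # neutral NE2-protonated tautomer by default
    "ASN": [("HD21", "ND2"), ("HD22", "ND2")],
    "GLN": [("HE21", "NE2"), ("HE22", "NE2")],
    "ARG": [("HE", "NE"), ("HH11", "NH1"), ("HH12", "NH1"),
            ("HH21", "NH2"), ("HH22", "NH2")],
    "LYS": [("HZ1", "NZ"), ("HZ2", "NZ"), ("HZ3", "NZ")],
}

# ideal X-H bond lengths by heavy-atom element
IDEAL_XH_BOND = {"O": 0.96, "N": 1.01, "S": 1.34}

# formal charges seeded before the PEOE iteration (ionized side chains)
SIDECHAIN_FORMAL_CHARGES: dict[str, dict[str, float]] = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": +1.0},
    "ARG": {"NH1": +0.5, "NH2": +0.5},
}


def normalize_element(element: str) -> str:
    return element.strip().upper()


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(normalize_element(element), DEFAULT_COVALENT_RADIUS)


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(normalize_element(element), DEFAULT_VDW_RADIUS)


def combine_lj(type_i: str, type_j: str) -> tuple[float, float]:
    """Lorentz-Berthelot combined (Rij, eps_ij) for two AD types."""
    pi, pj = AD4_ATOM_PARAMS[type_i], AD4_ATOM_PARAMS[type_j]
    return 0.5 * (pi.Rii + pj.Rii), math.sqrt(pi.eps_ii * pj.eps_ii)


def hbond_pair(type_i: str, type_j: str) -> tuple[float, float] | None:
    """(Rij_hb, eps_hb) if one atom is a polar H and the other an acceptor."""
    pi, pj = AD4_ATOM_PARAMS[type_i], AD4_ATOM_PARAMS[type_j]
    if pi.hbond_class == HB_DONOR_H and pj.hbond_class in (HB_ACC_O, HB_ACC_N, HB_ACC_S):
        return pj.Rij_hb, pj.eps_ij_hb
    if pj.hbond_class == HB_DONOR_H and pi.hbond_class in (HB_ACC_O, HB_ACC_N, HB_ACC_S):
        return pi.Rij_hb, pi.eps_ij_hb
    return None
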