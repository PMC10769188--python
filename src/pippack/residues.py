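"""Amino-acid constants: atom layouts, ideal internal coordinates, chi definitions.

Every residue is stored in a fixed 14-slot heavy-atom layout
(N, CA, C, O, CB, then side-chain atoms in build order).  Side-chain atoms
beyond CB are described by internal coordinates relative to three previously
placed parent atoms, with the torsion either tied to a chi angle (possibly
with a branch offset) or fixed (rigid ring geometry).  Bond lengths are in
Angstrom, angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# one- and three-letter codes, fixed ordering used for one-hot encodings
RESTYPES = [
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
]
RESTYPE_3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
N_RESTYPES = 20
RESTYPE_ORDER = {r: i for i, r in enumerate(RESTYPES)}
RESTYPE3_ORDER = {r: i for i, r in enumerate(RESTYPE_3)}
ONE_TO_THREE = dict(zip(RESTYPES, RESTYPE_3))
THREE_TO_ONE = dict(zip(RESTYPE_3, RESTYPES))

# common substitutions in deposited structures, mapped to the parent type
NONSTANDARD_PARENT = {"MSE": "MET", "SEC": "CYS", "MLY": "LYS", "HYP": "PRO"}

MAX_ATOMS = 14

ATOM14_NAMES = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}

BACKBONE_ATOMS = ["N", "CA", "C", "O"]
# Cbeta is treated as a main-chain atom for featurization purposes.
MAINCHAIN_ATOMS = ["N", "CA", "C", "O", "CB"]

# number of chi angles per residue type (three-letter keys)
CHI_COUNT = {
    "ALA": 0, "ARG": 4, "ASN": 2, "ASP": 2, "CYS": 1, "GLN": 3, "GLU": 3,
    "GLY": 0, "HIS": 2, "ILE": 2, "LEU": 2, "LYS": 4, "MET": 3, "PHE": 2,
    "PRO": 2, "SER": 1, "THR": 1, "TRP": 2, "TYR": 2, "VAL": 1,
}

# atom quadruples defining each chi dihedral
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# chi angles that are 180-degree symmetric (terminal group indistinguishable
# under a half-turn): value is the 1-based chi index
SYMMETRIC_CHI = {"ASP": 2, "GLU": 3, "PHE": 2, "TYR": 2}

# atom-name swaps that relabel symmetry-equivalent atoms (for RMSD scoring)
SYMMETRIC_SWAPS = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ARG": [("NH1", "NH2")],
}

# van der Waals radii per element (Angstrom)
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


def atom_element(name: str) -> str:
    """Element of a heavy atom from its PDB atom name."""
    return name.strip()[0]


# ---------------------------------------------------------------------------
# Side-chain build recipes.
#
# Each entry: (atom, (parent_a, parent_b, parent_c), bond, angle_deg, torsion)
# where the new atom X is bonded to parent_a with |X-a| = bond, the angle
# X-a-b equals angle_deg and the dihedral X-a-b-c equals the torsion rule:
#   ("chi", k, offset_deg) -> chi_k + offset_deg
#   ("fixed", value_deg)   -> constant (rigid ring geometry)
# CB is placed separately from the backbone (see geometry.ideal_cb).
# ---------------------------------------------------------------------------

SIDECHAIN_RECIPES = {
    "ALA": [],
    "GLY": [],
    "ARG": [
        ("CG", ("CB", "CA", "N"), 1.520, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.520, 111.5, ("chi", 2, 0.0)),
        ("NE", ("CD", "CG", "CB"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("NE", "CD", "CG"), 1.330, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CZ", "NE", "CD"), 1.326, 120.0, ("fixed", 0.0)),
        ("NH2", ("CZ", "NE", "CD"), 1.326, 120.0, ("fixed", 180.0)),
    ],
    "ASN": [
        ("CG", ("CB", "CA", "N"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CG", "CB", "CA"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CG", "CB", "CA"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "ASP": [
        ("CG", ("CB", "CA", "N"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CG", "CB", "CA"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CG", "CB", "CA"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "CYS": [
        ("SG", ("CB", "CA", "N"), 1.808, 114.2, ("chi", 1, 0.0)),
    ],
    "GLN": [
        ("CG", ("CB", "CA", "N"), 1.520, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CD", "CG", "CB"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CD", "CG", "CB"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "GLU": [
        ("CG", ("CB", "CA", "N"), 1.520, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CD", "CG", "CB"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", ("CD", "CG", "CB"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "HIS": [
        ("CG", ("CB", "CA", "N"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CG", "CB", "CA"), 1.371, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.356, 131.2, ("chi", 2, 180.0)),
        ("CE1", ("ND1", "CG", "CB"), 1.319, 109.0, ("fixed", 180.0)),
        ("NE2", ("CD2", "CG", "CB"), 1.374, 107.0, ("fixed", 180.0)),
    ],
    "ILE": [
        ("CG1", ("CB", "CA", "N"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", ("CG1", "CB", "CA"), 1.513, 113.9, ("chi", 2, 0.0)),
    ],
    "LEU": [
        ("CG", ("CB", "CA", "N"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.521, 110.5, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.521, 110.5, ("chi", 2, 122.0)),
    ],
    "LYS": [
        ("CG", ("CB", "CA", "N"), 1.520, 114.0, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.520, 111.5, ("chi", 2, 0.0)),
        ("CE", ("CD", "CG", "CB"), 1.520, 111.5, ("chi", 3, 0.0)),
        ("NZ", ("CE", "CD", "CG"), 1.489, 112.0, ("chi", 4, 0.0)),
    ],
    "MET": [
        ("CG", ("CB", "CA", "N"), 1.520, 114.0, ("chi", 1, 0.0)),
        ("SD", ("CG", "CB", "CA"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("SD", "CG", "CB"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "PHE": [
        ("CG", ("CB", "CA", "N"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CD1", "CG", "CB"), 1.382, 120.8, ("fixed", 180.0)),
        ("CE2", ("CD2", "CG", "CB"), 1.382, 120.8, ("fixed", 180.0)),
        ("CZ", ("CE1", "CD1", "CG"), 1.382, 120.0, ("fixed", 0.0)),
    ],
    "PRO": [
        ("CG", ("CB", "CA", "N"), 1.492, 104.5, ("chi", 1, 0.0)),
        ("CD", ("CG", "CB", "CA"), 1.503, 105.5, ("chi", 2, 0.0)),
    ],
    "SER": [
        ("OG", ("CB", "CA", "N"), 1.417, 110.8, ("chi", 1, 0.0)),
    ],
    "THR": [
        ("OG1", ("CB", "CA", "N"), 1.433, 109.5, ("chi", 1, 0.0)),
        ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "TRP": [
        ("CG", ("CB", "CA", "N"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.433, 126.6, ("chi", 2, 180.0)),
        ("NE1", ("CD1", "CG", "CB"), 1.374, 110.2, ("fixed", 180.0)),
        ("CE2", ("CD2", "CG", "CB"), 1.409, 107.2, ("fixed", 180.0)),
        ("CE3", ("CD2", "CG", "CB"), 1.398, 133.9, ("fixed", 0.0)),
        ("CZ2", ("CE2", "CD2", "CG"), 1.394, 122.4, ("fixed", 180.0)),
        ("CZ3", ("CE3", "CD2", "CG"), 1.382, 118.7, ("fixed", 180.0)),
        ("CH2", ("CZ2", "CE2", "CD2"), 1.368, 117.5, ("fixed", 0.0)),
    ],
    "TYR": [
        ("CG", ("CB", "CA", "N"), 1.512, 113.9, ("chi", 1, 0.0)),
        ("CD1", ("CG", "CB", "CA"), 1.389, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CG", "CB", "CA"), 1.389, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CD1", "CG", "CB"), 1.382, 121.1, ("fixed", 180.0)),
        ("CE2", ("CD2", "CG", "CB"), 1.382, 121.1, ("fixed", 180.0)),
        ("CZ", ("CE1", "CD1", "CG"), 1.378, 119.5, ("fixed", 0.0)),
        ("OH", ("CZ", "CE1", "CD1"), 1.376, 119.9, ("fixed", 180.0)),
    ],
    "VAL": [
        ("CG1", ("CB", "CA", "N"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("CB", "CA", "N"), 1.521, 110.5, ("chi", 1, 122.0)),
    ],
}

# ideal backbone internal coordinates used by the fixture generator
BACKBONE_GEOMETRY = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond
    ("C", "O"): 1.231,
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 116.2,
    ("C", "N", "CA"): 121.7,
    ("CA", "C", "O"): 120.8,
}

PRO_CD_N_BOND = 1.474  # ideal proline ring-closing Cdelta-N distance


@dataclass(frozen=True)
class IdealGeometry:
    """Handle over the constant side-chain geometry tables.

    Kept as a lightweight object so geometry-consuming functions take it as an
    explicit argument; all instances share the module-level tables.
    """

    atom_names = ATOM14_NAMES
    recipes = SIDECHAIN_RECIPES
    chi_atoms = CHI_ATOMS
    chi_count = CHI_COUNT
    symmetric_chi = SYMMETRIC_CHI
    vdw_radii = VDW_RADII
    pro_cd_n_bond = PRO_CD_N_BOND

    def atom_index(self, resname: str, atom: str) -> int:
        return ATOM14_NAMES[resname].index(atom)

    def vdw_radius(self, atom_name: str) -> float:
        return VDW_RADII[atom_element(atom_name)]


IDEAL_GEOMETRY = IdealGeometry()

# per-restype index arrays, precomputed for vectorized consumers -------------

# chi mask by residue type index: (20, 4) bool
CHI_MASK_BY_RESTYPE = np.zeros((N_RESTYPES, 4), dtype=bool)
for _res3, _n in CHI_COUNT.items():
    CHI_MASK_BY_RESTYPE[RESTYPE3_ORDER[_res3], :_n] = True

# chi-defining atom14 indices by residue type: (20, 4, 4), -1 where undefined
CHI_ATOM14_IDX = np.full((N_RESTYPES, 4, 4), -1, dtype=np.int64)
for _res3, _quads in CHI_ATOMS.items():
    _ri = RESTYPE3_ORDER[_res3]
    for _k, _quad in enumerate(_quads):
        for _a, _name in enumerate(_quad):
            CHI_ATOM14_IDX[_ri, _k, _a] = ATOM14_NAMES[_res3].index(_name)

# atom14 presence mask by residue type: (20, 14)
ATOM14_EXISTS = np.zeros((N_RESTYPES, MAX_ATOMS), dtype=bool)
for _res3, _names in ATOM14_NAMES.items():
    ATOM14_EXISTS[RESTYPE3_ORDER[_res3], : len(_names)] = True

# vdW radius per atom14 slot by residue type: (20, 14), 0 where no atom
ATOM14_VDW = np.zeros((N_RESTYPES, MAX_ATOMS))
for _res3, _names in ATOM14_NAMES.items():
    for _i, _name in enumerate(_names):
        ATOM14_VDW[RESTYPE3_ORDER[_res3], _i] = VDW_RADII[atom_element(_name)]

# 180-symmetric chi flags: (20, 4)
CHI_SYMMETRIC = np.zeros((N_RESTYPES, 4), dtype=bool)
for _res3, _k in SYMMETRIC_CHI.items():
    CHI_SYMMETRIC[RESTYPE3_ORDER[_res3], _k - 1] = True


def intra_residue_bonds(resname: str) -> list[tuple[int, int]]:
    """Bonded atom14 index pairs within one residue (heavy atoms only)."""
    names = ATOM14_NAMES[resname]
    idx = {n: i for i, n in enumerate(names)}
    bonds = [(idx["N"], idx["CA"]), (idx["CA"], idx["C"]), (idx["C"], idx["O"])]
    if "CB" in idx:
        bonds.append((idx["CA"], idx["CB"]))
    for atom, parents, *_ in SIDECHAIN_RECIPES[resname]:
        bonds.append((idx[atom], idx[parents[0]]))
    if resname == "PRO":
        bonds.append((idx["CD"], idx["N"]))  # ring closure
    return bonds


def seq_to_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([RESTYPE_ORDER[c] for c in sequence], dtype=np.int64)
    except KeyError as err:
        raise ValueError(f"unknown residue code in sequence: {err}") from err


def indices_to_seq(indices: np.ndarray) -> str:
    return "".join(RESTYPES[int(i)] for i in indices)
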