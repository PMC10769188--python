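"""Protein chain container, PDB I/O and torsion-space structure operations.

A :class:`ProteinChain` stores one polypeptide chain in a fixed 14-slot
heavy-atom layout per residue (N, CA, C, O, CB, side chain).  Side chains can
be stripped to torsion angles (:func:`extract_chi`) and rebuilt from torsions
with ideal bond lengths and angles (:func:`build_side_chains`); the two
operations are exact inverses for ideally built side chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import ops as A
from . import residues as R
from .geometry import (RigidTransform, dihedral, frames_from_backbone,
                       ideal_cb, place_atom, wrap_angle)

logger = logging.getLogger(__name__)

_N, _CA, _C, _O, _CB = 0, 1, 2, 3, 4


@dataclass
class ProteinChain:
    """One protein chain in atom14 layout.

    Attributes
    ----------
    sequence:
        One-letter amino-acid string of length L.
    atom_coords:
        (L, 14, 3) heavy-atom coordinates in Angstrom.
    atom_mask:
        (L, 14) presence flags; slots a residue type does not define are False.
    b_factors:
        (L, 14) per-atom B-factors in A^2 (0 where unknown).
    residue_ids:
        (L,) author residue numbers, kept for round-trip I/O.
    """

    sequence: str
    atom_coords: np.ndarray
    atom_mask: np.ndarray
    b_factors: np.ndarray = None
    residue_ids: np.ndarray = None
    chain_id: str = "A"
    aatype: np.ndarray = field(init=False)

    def __post_init__(self):
        self.aatype = R.seq_to_indices(self.sequence)
        L = len(self.sequence)
        self.atom_coords = np.asarray(self.atom_coords, dtype=np.float64)
        self.atom_mask = np.asarray(self.atom_mask, dtype=bool)
        if self.b_factors is None:
            self.b_factors = np.zeros((L, R.MAX_ATOMS))
        self.b_factors = np.asarray(self.b_factors, dtype=np.float64)
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, L + 1, dtype=np.int64)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self):
        L = len(self.sequence)
        for name, arr, shape in [
            ("atom_coords", self.atom_coords, (L, R.MAX_ATOMS, 3)),
            ("atom_mask", self.atom_mask, (L, R.MAX_ATOMS)),
            ("b_factors", self.b_factors, (L, R.MAX_ATOMS)),
            ("residue_ids", self.residue_ids, (L,)),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if not np.all(np.isfinite(self.atom_coords[self.atom_mask])):
            raise ValueError("non-finite coordinates for present atoms")
        has_sc = self.atom_mask[:, _CB:].any(axis=1)
        bb_ok = self.atom_mask[:, [_N, _CA, _C]].all(axis=1)
        if np.any(has_sc & ~bb_ok):
            bad = int(np.nonzero(has_sc & ~bb_ok)[0][0])
            raise ValueError(
                f"residue {bad} has side-chain atoms but incomplete N/CA/C backbone")

    # -- convenience accessors --------------------------------------------
    @property
    def backbone_coords(self) -> np.ndarray:
        """(L, 4, 3) N, CA, C, O coordinates."""
        return self.atom_coords[:, :4]

    def atom_positions(self, name: str) -> np.ndarray:
        """(L, 3) coordinates of a named backbone slot (N/CA/C/O/CB)."""
        idx = {"N": _N, "CA": _CA, "C": _C, "O": _O, "CB": _CB}[name]
        return self.atom_coords[:, idx]

    def cb_or_virtual(self) -> np.ndarray:
        """(L, 3) C-beta coordinates, ideally constructed where absent (GLY)."""
        cb = self.atom_coords[:, _CB].copy()
        missing = ~self.atom_mask[:, _CB]
        if missing.any():
            cb[missing] = ideal_cb(self.atom_coords[missing, _N],
                                   self.atom_coords[missing, _CA],
                                   self.atom_coords[missing, _C])
        return cb

    def copy(self) -> "ProteinChain":
        return ProteinChain(self.sequence, self.atom_coords.copy(),
                            self.atom_mask.copy(), self.b_factors.copy(),
                            self.residue_ids.copy(), self.chain_id)

    def transformed(self, transform: RigidTransform) -> "ProteinChain":
        """Chain with all present atoms moved by a global rigid transform."""
        coords = self.atom_coords.copy()
        coords[self.atom_mask] = transform.apply(coords[self.atom_mask])
        return ProteinChain(self.sequence, coords, self.atom_mask.copy(),
                            self.b_factors.copy(), self.residue_ids.copy(),
                            self.chain_id)


@dataclass
class ChiAngles:
    """Side-chain dihedrals: (L, 4) radians in [-pi, pi) plus a validity mask."""

    chi: np.ndarray
    chi_mask: np.ndarray

    def __post_init__(self):
        self.chi = np.asarray(self.chi, dtype=np.float64)
        self.chi_mask = np.asarray(self.chi_mask, dtype=bool)


# -- PDB I/O ----------------------------------------------------------------

def read_pdb_chain(path, chain_id: str = "A") -> ProteinChain:
    """Read one chain from a PDB file into atom14 layout.

    Alternate locations are resolved to the highest occupancy; residues that
    cannot be mapped to one of the 20 canonical types are dropped with a
    warning; atoms outside the atom14 layout (hydrogens, OXT) are ignored.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy",
                              extra_fields=["b_factor"])
    atoms = atoms[atoms.chain_id == chain_id]
    if atoms.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} not found in {path}")
    atoms = atoms[bst.filter_amino_acids(atoms)]

    seq, coords, mask, bfac, res_ids = [], [], [], [], []
    for res in bst.residue_iter(atoms):
        resname = res.res_name[0]
        if resname in R.NONSTANDARD_PARENT:
            resname = R.NONSTANDARD_PARENT[resname]
        if resname not in R.RESTYPE3_ORDER:
            logger.warning("dropping non-canonical residue %s %d",
                           res.res_name[0], int(res.res_id[0]))
            continue
        names = R.ATOM14_NAMES[resname]
        xyz = np.zeros((R.MAX_ATOMS, 3))
        m = np.zeros(R.MAX_ATOMS, dtype=bool)
        b = np.zeros(R.MAX_ATOMS)
        for i in range(res.array_length()):
            name = res.atom_name[i]
            if name == "SE" and res.res_name[0] == "MSE":
                name = "SD"
            if name in names:
                j = names.index(name)
                xyz[j] = res.coord[i]
                m[j] = True
                b[j] = res.b_factor[i]
        if not m[[_N, _CA, _C]].all():
            # keep backbone-incomplete residues only if fully side-chain free
            m[_CB:] = False
            xyz[_CB:] = 0.0
        seq.append(R.THREE_TO_ONE[resname])
        coords.append(xyz)
        mask.append(m)
        bfac.append(b)
        res_ids.append(int(res.res_id[0]))
    if not seq:
        raise ValueError(f"empty chain: no parsable residues in chain {chain_id!r}")
    return ProteinChain("".join(seq), np.stack(coords), np.stack(mask),
                        np.stack(bfac), np.array(res_ids), chain_id)


def write_pdb_chain(chain: ProteinChain, path) -> None:
    """Write standard ATOM records (occupancy 1.00); masked atoms are omitted."""
    if len(chain) == 0:
        raise ValueError("cannot write an empty chain")
    n_atoms = int(chain.atom_mask.sum())
    arr = bst.AtomArray(n_atoms)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    k = 0
    for i, aa in enumerate(chain.sequence):
        res3 = R.ONE_TO_THREE[aa]
        for j, name in enumerate(R.ATOM14_NAMES[res3]):
            if not chain.atom_mask[i, j]:
                continue
            arr.coord[k] = chain.atom_coords[i, j]
            arr.chain_id[k] = chain.chain_id
            arr.res_id[k] = chain.residue_ids[i]
            arr.res_name[k] = res3
            arr.atom_name[k] = name
            arr.element[k] = R.atom_element(name)
            arr.hetero[k] = False
            arr.b_factor[k] = chain.b_factors[i, j]
            arr.occupancy[k] = 1.0
            k += 1
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# -- backbone geometry ------------------------------------------------------

def backbone_frames(chain: ProteinChain) -> RigidTransform:
    """Per-residue rigid frame from N/CA/C (translation at CA)."""
    if not chain.atom_mask[:, [_N, _CA, _C]].all():
        bad = int(np.nonzero(~chain.atom_mask[:, [_N, _CA, _C]].all(axis=1))[0][0])
        raise ValueError(f"missing backbone atom at residue index {bad}")
    return frames_from_backbone(chain.atom_coords[:, _N],
                                chain.atom_coords[:, _CA],
                                chain.atom_coords[:, _C])


def backbone_dihedrals(chain: ProteinChain):
    """(phi, psi, omega) per residue with validity masks.

    omega(i) is the dihedral of the peptide bond preceding residue i,
    CA(i-1)-C(i-1)-N(i)-CA(i).  Undefined at the termini: phi and omega of
    the first residue, psi of the last.

    Returns
    -------
    angles : (L, 3) radians in [-pi, pi), zero where masked.
    mask : (L, 3) bool.
    """
    L = len(chain)
    x = chain.atom_coords
    m = chain.atom_mask
    angles = np.zeros((L, 3))
    mask = np.zeros((L, 3), dtype=bool)
    if L >= 2:
        prev_ok = m[:-1, [_N, _CA, _C]].all(axis=1)
        cur_ok = m[1:, [_N, _CA, _C]].all(axis=1)
        ok = prev_ok & cur_ok
        # phi(i) = C(i-1), N(i), CA(i), C(i)
        angles[1:, 0] = np.where(
            ok, dihedral(x[:-1, _C], x[1:, _N], x[1:, _CA], x[1:, _C]), 0.0)
        mask[1:, 0] = ok
        # psi(i) = N(i), CA(i), C(i), N(i+1)
        angles[:-1, 1] = np.where(
            ok, dihedral(x[:-1, _N], x[:-1, _CA], x[:-1, _C], x[1:, _N]), 0.0)
        mask[:-1, 1] = ok
        # omega(i) = CA(i-1), C(i-1), N(i), CA(i)
        angles[1:, 2] = np.where(
            ok, dihedral(x[:-1, _CA], x[:-1, _C], x[1:, _N], x[1:, _CA]), 0.0)
        mask[1:, 2] = ok
    return wrap_angle(angles) * mask, mask


# -- chi angles -------------------------------------------------------------

def extract_chi(chain: ProteinChain, geometry: R.IdealGeometry = R.IDEAL_GEOMETRY
                ) -> ChiAngles:
    """Measure side-chain dihedrals from coordinates.

    Entries are masked where the residue type defines no such chi or any
    defining atom is absent.
    """
    L = len(chain)
    chi = np.zeros((L, 4))
    chi_mask = np.zeros((L, 4), dtype=bool)
    quad_idx = R.CHI_ATOM14_IDX[chain.aatype]          # (L, 4, 4)
    defined = R.CHI_MASK_BY_RESTYPE[chain.aatype]      # (L, 4)
    for k in range(4):
        idx = quad_idx[:, k, :]                        # (L, 4)
        ok = defined[:, k].copy()
        safe = np.where(idx < 0, 0, idx)
        present = np.take_along_axis(chain.atom_mask, safe, axis=1).all(axis=1)
        ok &= present
        if not ok.any():
            continue
        pts = np.take_along_axis(chain.atom_coords[ok],
                                 safe[ok][:, :, None].repeat(3, axis=2), axis=1)
        chi[ok, k] = dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        chi_mask[ok, k] = True
    return ChiAngles(chi * chi_mask, chi_mask)


def place_side_chain_atoms(chain: ProteinChain, chi,
                           geometry: R.IdealGeometry = R.IDEAL_GEOMETRY):
    """Side-chain atom positions from chi angles with ideal geometry.

    ``chi`` is an (L, 4) array or Tensor of radians; the return value is a
    dict mapping (residue_index, atom14_slot) -> position (3-vector, Tensor
    when chi is a Tensor).  CB is included (ideally placed; constant w.r.t.
    chi).  Used by :func:`build_side_chains` and, with Tensors, by the
    differentiable finetuning losses.
    """
    placed = {}
    x = chain.atom_coords
    for i, aa in enumerate(chain.sequence):
        res3 = R.ONE_TO_THREE[aa]
        if res3 == "GLY":
            continue
        names = R.ATOM14_NAMES[res3]
        pos = {"N": x[i, _N], "CA": x[i, _CA], "C": x[i, _C]}
        cb = ideal_cb(x[i, _N], x[i, _CA], x[i, _C])
        pos["CB"] = cb
        placed[(i, _CB)] = cb
        for atom, parents, bond, angle_deg, rule in R.SIDECHAIN_RECIPES[res3]:
            if rule[0] == "chi":
                _, k, offset_deg = rule
                torsion = A.add(_chi_entry(chi, i, k - 1), np.deg2rad(offset_deg))
            else:
                torsion = np.deg2rad(rule[1])
            p = place_atom(pos[parents[0]], pos[parents[1]], pos[parents[2]],
                           bond, np.deg2rad(angle_deg), torsion)
            pos[atom] = p
            placed[(i, names.index(atom))] = p
    return placed


def _chi_entry(chi, i, k):
    if A.is_tensor(chi):
        return chi[i, k]
    return np.asarray(chi)[i, k]


def build_side_chains(chain: ProteinChain, chi: ChiAngles,
                      geometry: R.IdealGeometry = R.IDEAL_GEOMETRY
                      ) -> ProteinChain:
    """Rebuild all side-chain heavy atoms (including CB) from chi angles.

    Backbone N/CA/C/O coordinates are kept from the input.  Residues whose
    type requires a chi that is masked off raise an error.
    """
    need = R.CHI_MASK_BY_RESTYPE[chain.aatype]
    missing = need & ~chi.chi_mask
    if missing.any():
        bad = int(np.nonzero(missing.any(axis=1))[0][0])
        raise ValueError(f"residue {bad} is missing a required chi angle")
    coords = chain.atom_coords.copy()
    mask = chain.atom_mask.copy()
    placed = place_side_chain_atoms(chain, chi.chi, geometry)
    for (i, j), p in placed.items():
        coords[i, j] = A.as_array(p)
        mask[i, j] = True
    # only slots the residue type defines
    mask &= R.ATOM14_EXISTS[chain.aatype]
    coords[~mask] = 0.0
    return ProteinChain(chain.sequence, coords, mask, chain.b_factors.copy(),
                        chain.residue_ids.copy(), chain.chain_id)
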