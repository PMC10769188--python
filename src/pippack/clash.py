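"""Steric overlap detection and penalties.

Two atoms clash when the sum of their van der Waals radii exceeds their
distance.  Pairs connected by at most two covalent bonds are excluded, as
are main-chain/main-chain pairs of the same or sequence-adjacent residues
(those distances are fixed by the input backbone, not by packing).  The
quadratic overlap penalty doubles as the energy for Metropolis resampling;
the hard-threshold count (overlap > 0.4 A) drives the clashscore proxy and
the clashing-residue detector.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import ops as A
from . import residues as R
from .structure import ProteinChain

_MAINCHAIN_SLOTS = frozenset(range(5))  # N, CA, C, O, CB
_MAX_RSUM = 2 * max(R.VDW_RADII.values())
CLASH_OVERLAP_CUT = 0.4  # Angstrom, serious-clash threshold


def atom_entries(chain: ProteinChain):
    """(residue_index, atom14_slot) arrays for all present heavy atoms."""
    res_idx, slot_idx = np.nonzero(chain.atom_mask)
    return res_idx, slot_idx


def _bond_adjacency(chain: ProteinChain, res_idx, slot_idx):
    """Neighbor sets over flat atom indices from the covalent bond graph."""
    n = len(res_idx)
    flat = {(int(r), int(s)): a for a, (r, s) in enumerate(zip(res_idx, slot_idx))}
    adj = [set() for _ in range(n)]

    def connect(key_a, key_b):
        ia, ib = flat.get(key_a), flat.get(key_b)
        if ia is not None and ib is not None:
            adj[ia].add(ib)
            adj[ib].add(ia)

    for i, aa in enumerate(chain.sequence):
        res3 = R.ONE_TO_THREE[aa]
        for sa, sb in R.intra_residue_bonds(res3):
            connect((i, sa), (i, sb))
    for i in range(len(chain) - 1):
        connect((i, 2), (i + 1, 0))  # peptide C(i)-N(i+1)
    return adj


def excluded_pair_set(chain: ProteinChain) -> set:
    """Flat atom-index pairs (a < b) excluded from clash consideration."""
    res_idx, slot_idx = atom_entries(chain)
    adj = _bond_adjacency(chain, res_idx, slot_idx)
    excluded = set()
    for a, neighbors in enumerate(adj):
        reach = set(neighbors)
        for b in neighbors:
            reach |= adj[b]
        for b in reach:
            if b != a:
                excluded.add((min(a, b), max(a, b)))
    mainchain = np.isin(slot_idx, list(_MAINCHAIN_SLOTS))
    close_res = np.abs(res_idx[:, None] - res_idx[None, :]) <= 1
    both_mc = mainchain[:, None] & mainchain[None, :]
    for a, b in zip(*np.nonzero(np.triu(close_res & both_mc, k=1))):
        excluded.add((int(a), int(b)))
    return excluded


def candidate_pairs(chain: ProteinChain, geometry: R.IdealGeometry = R.IDEAL_GEOMETRY):
    """Non-excluded atom pairs close enough to possibly overlap.

    Returns (pair_index_array (m, 2), radius_sums (m,), res_idx, slot_idx).
    Pairs are found with a KD-tree at the maximum radius sum, so any pair
    with positive overlap is guaranteed to be included.
    """
    res_idx, slot_idx = atom_entries(chain)
    coords = chain.atom_coords[res_idx, slot_idx]
    radii = R.ATOM14_VDW[chain.aatype[res_idx], slot_idx]
    if len(coords) < 2:
        return np.zeros((0, 2), dtype=int), np.zeros(0), res_idx, slot_idx
    tree = cKDTree(coords)
    raw = tree.query_pairs(r=_MAX_RSUM, output_type="ndarray")
    excluded = excluded_pair_set(chain)
    keep = np.array([tuple(p) not in excluded for p in np.sort(raw, axis=1)],
                    dtype=bool) if len(raw) else np.zeros(0, dtype=bool)
    pairs = raw[keep]
    rsum = radii[pairs[:, 0]] + radii[pairs[:, 1]] if len(pairs) else np.zeros(0)
    return pairs, rsum, res_idx, slot_idx


def pair_overlaps(chain: ProteinChain, geometry: R.IdealGeometry = R.IDEAL_GEOMETRY):
    """Positive-overlap pairs: ((m, 2) pair residue indices, (m,) overlaps in A)."""
    pairs, rsum, res_idx, _ = candidate_pairs(chain, geometry)
    if not len(pairs):
        return np.zeros((0, 2), dtype=int), np.zeros(0)
    coords = chain.atom_coords[chain.atom_mask]
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=-1)
    overlap = rsum - d
    pos = overlap > 0
    return np.stack([res_idx[pairs[pos, 0]], res_idx[pairs[pos, 1]]], axis=1), \
        overlap[pos]


def clash_loss(chain: ProteinChain,
               geometry: R.IdealGeometry = R.IDEAL_GEOMETRY) -> float:
    """Sum of squared vdW overlaps over non-excluded atom pairs."""
    _, overlaps = pair_overlaps(chain, geometry)
    return float(np.sum(overlaps ** 2))


def clash_loss_from_positions(chain: ProteinChain, placed: dict,
                              geometry: R.IdealGeometry = R.IDEAL_GEOMETRY):
    """Differentiable clash penalty.

    ``placed`` maps (residue, slot) -> position (Tensor or array) for
    side-chain atoms; remaining coordinates are taken from ``chain``, whose
    numeric coordinates must already agree with ``placed`` (the pair list is
    derived from them).
    """
    pairs, rsum, res_idx, slot_idx = candidate_pairs(chain, geometry)
    if not len(pairs):
        return A.Tensor(0.0)
    positions = [placed.get((int(r), int(s)), chain.atom_coords[r, s])
                 for r, s in zip(res_idx, slot_idx)]
    coords = A.stack(positions, axis=0)
    diff = A.sub(A.take(coords, pairs[:, 0]), A.take(coords, pairs[:, 1]))
    d = A.norm(diff, axis=-1, eps=1e-12)
    return A.sum_(A.relu(A.sub(rsum, d)) ** 2)


def find_clashing_residues(chain: ProteinChain,
                           geometry: R.IdealGeometry = R.IDEAL_GEOMETRY,
                           overlap_cut: float = CLASH_OVERLAP_CUT) -> set:
    """Residues owning an atom in a pair with vdW overlap above the cutoff."""
    pair_res, overlaps = pair_overlaps(chain, geometry)
    serious = overlaps > overlap_cut
    return set(pair_res[serious].ravel().tolist())


def clashscore(chain: ProteinChain,
               geometry: R.IdealGeometry = R.IDEAL_GEOMETRY,
               overlap_cut: float = CLASH_OVERLAP_CUT) -> float:
    """Serious steric clashes (overlap > 0.4 A) per 1000 heavy atoms.

    A heavy-atom proxy for the MolProbity clashscore: no hydrogens are
    modeled and overlap is a simple radius-sum criterion rather than a
    dot-surface computation, so absolute values are not comparable with
    MolProbity's, only relative ones.
    """
    _, overlaps = pair_overlaps(chain, geometry)
    n_atoms = int(chain.atom_mask.sum())
    if n_atoms == 0:
        return 0.0
    return 1000.0 * float(np.sum(overlaps > overlap_cut)) / n_atoms


# -- proline ring closure ---------------------------------------------------

def proline_cd_n_deviation(chain: ProteinChain) -> np.ndarray:
    """|d(Cdelta, N) - ideal| per proline residue (aligned with pro indices)."""
    idx = proline_indices(chain)
    if not len(idx):
        return np.zeros(0)
    cd_slot = R.ATOM14_NAMES["PRO"].index("CD")
    d = np.linalg.norm(chain.atom_coords[idx, cd_slot] -
                       chain.atom_coords[idx, 0], axis=-1)
    return np.abs(d - R.PRO_CD_N_BOND)


def proline_indices(chain: ProteinChain) -> np.ndarray:
    cd_slot = R.ATOM14_NAMES["PRO"].index("CD")
    pro = chain.aatype == R.RESTYPE3_ORDER["PRO"]
    return np.nonzero(pro & chain.atom_mask[:, cd_slot])[0]


def proline_closure_loss(chain: ProteinChain, placed: dict = None):
    """Sum of squared Cdelta-N bond-length deviations over prolines.

    Differentiable when ``placed`` supplies Tensor positions for CD.
    """
    idx = proline_indices(chain)
    if not len(idx):
        return 0.0 if placed is None else A.Tensor(0.0)
    cd_slot = R.ATOM14_NAMES["PRO"].index("CD")
    if placed is None:
        dev = proline_cd_n_deviation(chain)
        return float(np.sum(dev ** 2))
    terms = []
    for i in idx:
        cd = placed.get((int(i), cd_slot), chain.atom_coords[i, cd_slot])
        d = A.norm(A.sub(cd, chain.atom_coords[i, 0]), axis=-1, eps=1e-12)
        terms.append((d - R.PRO_CD_N_BOND) ** 2)
    total = terms[0]
    for t in terms[1:]:
        total = A.add(total, t)
    return total
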