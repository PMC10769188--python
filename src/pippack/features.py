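"""Residue-graph construction and featurization.

Every feature produced here is a function of sequence separations, dihedral
angles and interatomic distances only, and is therefore invariant under
global rigid motions of the input coordinates.  The per-residue backbone
frames carried alongside the graph are the only equivariant quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import residues as R
from .geometry import RigidTransform
from .structure import ChiAngles, ProteinChain, backbone_dihedrals, backbone_frames

# default featurization constants
K_NEIGHBORS = 30
RELPOS_CLIP = 32
RBF_BINS = 16
RBF_MIN = 0.0
RBF_MAX = 20.0

NODE_DIM = R.N_RESTYPES + 6                 # one-hot + sin/cos of phi/psi/omega
EDGE_DIM = (2 * RELPOS_CLIP + 1) + 25 * RBF_BINS
RECYCLE_NODE_DIM = 8                        # sin/cos of 4 chi
RECYCLE_EDGE_DIM = 3 * RBF_BINS             # sc-bb, bb-sc, sc-sc distances

_FAR = 1e3  # distance stand-in when a residue has no side-chain atoms


@dataclass
class ResidueGraph:
    """k-NN residue graph with raw (pre-projection) feature matrices."""

    node_features: np.ndarray       # (L, NODE_DIM)
    edge_features: np.ndarray       # (L, k, EDGE_DIM)
    neighbor_idx: np.ndarray        # (L, k) int
    edge_mask: np.ndarray           # (L, k) bool
    frames: RigidTransform          # per-residue backbone frames
    recycle_node: np.ndarray = None  # (L, RECYCLE_NODE_DIM)
    recycle_edge: np.ndarray = None  # (L, k, RECYCLE_EDGE_DIM)

    def __post_init__(self):
        L, k = self.neighbor_idx.shape
        if self.recycle_node is None:
            self.recycle_node = np.zeros((L, RECYCLE_NODE_DIM))
        if self.recycle_edge is None:
            self.recycle_edge = np.zeros((L, k, RECYCLE_EDGE_DIM))

    @property
    def n_residues(self) -> int:
        return self.node_features.shape[0]

    @property
    def k(self) -> int:
        return self.neighbor_idx.shape[1]


def knn_graph(chain: ProteinChain, k: int = K_NEIGHBORS):
    """k nearest neighbors per residue by CA-CA distance.

    Neighbors are sorted by ascending distance with ties broken by the lower
    residue index; self-edges are excluded.  When fewer than k other residues
    exist the remaining slots are masked out.

    Returns (neighbor_idx, edge_mask), both (L, k).
    """
    L = len(chain)
    if L < 2:
        raise ValueError("k-NN graph requires at least 2 residues")
    ca = chain.atom_positions("CA")
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # round before sorting so exact-tie orderings (ideal secondary structure)
    # stay stable under floating-point perturbations of a rigid motion
    order = np.lexsort((np.broadcast_to(np.arange(L), (L, L)), np.round(d, 6)),
                       axis=1)
    n_valid = min(k, L - 1)
    neighbor_idx = np.empty((L, k), dtype=np.int64)
    neighbor_idx[:, :n_valid] = order[:, :n_valid]
    edge_mask = np.zeros((L, k), dtype=bool)
    edge_mask[:, :n_valid] = True
    if n_valid < k:  # pad with an arbitrary non-self index, masked out
        pad = (np.arange(L)[:, None] + 1) % L
        neighbor_idx[:, n_valid:] = pad
    return neighbor_idx, edge_mask


def rbf_encode(d, n_bins: int = RBF_BINS, d_min: float = RBF_MIN,
               d_max: float = RBF_MAX) -> np.ndarray:
    """Gaussian radial basis encoding of distances.

    Centers are evenly spaced on [d_min, d_max]; the width equals the center
    spacing.  Input of any shape (...) maps to (..., n_bins).
    """
    centers = np.linspace(d_min, d_max, n_bins)
    sigma = (d_max - d_min) / (n_bins - 1)
    z = (np.asarray(d, dtype=np.float64)[..., None] - centers) / sigma
    return np.exp(-z * z)


def node_features(chain: ProteinChain) -> np.ndarray:
    """Sequence one-hot plus sin/cos of (phi, psi, omega); masked angles -> (0, 0)."""
    L = len(chain)
    onehot = np.zeros((L, R.N_RESTYPES))
    onehot[np.arange(L), chain.aatype] = 1.0
    angles, mask = backbone_dihedrals(chain)
    trig = np.concatenate([np.sin(angles) * mask, np.cos(angles) * mask], axis=1)
    return np.concatenate([onehot, trig], axis=1)


def edge_features(chain: ProteinChain, neighbor_idx: np.ndarray,
                  relpos_clip: int = RELPOS_CLIP) -> np.ndarray:
    """Relative-position one-hot and RBF-encoded backbone atom distances.

    For each edge i->j the 25 ordered distances between the five main-chain
    atoms (N, CA, C, O, CB; glycine gets a virtual CB) of i and of j are RBF
    encoded and concatenated after the clipped sequence-offset one-hot.
    """
    L, k = neighbor_idx.shape
    offsets = np.clip(neighbor_idx - np.arange(L)[:, None],
                      -relpos_clip, relpos_clip) + relpos_clip
    relpos = np.zeros((L, k, 2 * relpos_clip + 1))
    ii, kk = np.meshgrid(np.arange(L), np.arange(k), indexing="ij")
    relpos[ii, kk, offsets] = 1.0

    bb = np.concatenate([chain.backbone_coords,
                         chain.cb_or_virtual()[:, None, :]], axis=1)  # (L, 5, 3)
    bi = bb[:, None, :, None, :]            # (L, 1, 5, 1, 3)
    bj = bb[neighbor_idx][:, :, None, :, :]  # (L, k, 1, 5, 3)
    d = np.linalg.norm(bi - bj, axis=-1)     # (L, k, 5, 5)
    rbf = rbf_encode(d).reshape(L, k, 25 * RBF_BINS)
    return np.concatenate([relpos, rbf], axis=2)


def recycling_features(chain_with_sc: ProteinChain, chi_pred: ChiAngles,
                       neighbor_idx: np.ndarray):
    """Features carrying the previous prediction into the next pass.

    Node augment: sin/cos of the four predicted chi angles (masked -> zeros).
    Edge augment: RBF encodings of the minimum heavy-atom distances between
    (side chain_i, backbone_j), (backbone_i, side chain_j) and
    (side chain_i, side chain_j) for each edge.
    """
    chi = chi_pred.chi * chi_pred.chi_mask
    m = chi_pred.chi_mask
    node_aug = np.concatenate([np.sin(chi) * m, np.cos(chi) * m], axis=1)

    coords = chain_with_sc.atom_coords
    sc_mask = chain_with_sc.atom_mask.copy()
    sc_mask[:, :5] = False                   # side chain = beyond CB
    bb_mask = chain_with_sc.atom_mask.copy()
    bb_mask[:, 5:] = False

    # distances restricted to graph edges: (L, k, 14, 14)
    d = np.linalg.norm(coords[:, None, :, None, :] -
                       coords[neighbor_idx][:, :, None, :, :], axis=-1)
    mi = {"sc": sc_mask[:, None, :, None], "bb": bb_mask[:, None, :, None]}
    mj = {"sc": sc_mask[neighbor_idx][:, :, None, :],
          "bb": bb_mask[neighbor_idx][:, :, None, :]}
    edge_aug = np.concatenate([
        rbf_encode(_masked_min(d, mi["sc"], mj["bb"])),
        rbf_encode(_masked_min(d, mi["bb"], mj["sc"])),
        rbf_encode(_masked_min(d, mi["sc"], mj["sc"])),
    ], axis=2)
    return node_aug, edge_aug


def _masked_min(d, mask_i, mask_j):
    """Minimum over atom pairs with both atoms present; _FAR when none."""
    dm = np.where(mask_i & mask_j, d, np.inf).min(axis=(2, 3))
    return np.where(np.isfinite(dm), dm, _FAR)


def featurize(chain: ProteinChain, k: int = K_NEIGHBORS) -> ResidueGraph:
    """Build the full input graph for a chain (first-pass: zero recycle blocks)."""
    neighbor_idx, edge_mask = knn_graph(chain, k)
    return ResidueGraph(
        node_features=node_features(chain),
        edge_features=edge_features(chain, neighbor_idx),
        neighbor_idx=neighbor_idx,
        edge_mask=edge_mask,
        frames=backbone_frames(chain),
    )
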