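"""The side-chain packing network.

An invariant graph neural network over the k-NN residue graph: node and edge
features are projected into a hidden space, processed by a stack of message
passing layers (plain MPNN, neighborhood invariant point attention, or
invariant point message passing), and decoded by a classification head into
per-residue, per-chi logits over angular bins plus per-bin offsets.
Predictions can be refined by recycling: between passes the current modes
are decoded, side chains rebuilt, and recycling features recomputed.  All
layer outputs are invariant under global rigid motions of the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import binning
from . import features as F
from . import nn
from . import ops as A
from . import residues as R
from .geometry import RigidTransform
from .structure import ChiAngles, ProteinChain, build_side_chains

CHECKPOINT_VERSION = "pippack-checkpoint-1"

LAYER_TYPES = ("mpnn", "ipa", "ipmp")


@dataclass
class PIPPackConfig:
    hidden_dim: int = 128
    edge_dim: int = 128
    n_layers: int = 3
    layer_type: str = "ipmp"
    n_points: int = 8
    mlp_depth: int = 2
    n_bins: int = binning.N_BINS
    n_recycles: int = 3
    k_neighbors: int = F.K_NEIGHBORS
    ipa_heads: int = 4
    ipa_channels: int = 16
    ipa_query_points: int = 4
    ipa_value_points: int = 8

    def __post_init__(self):
        if self.layer_type not in LAYER_TYPES:
            raise ValueError(f"layer_type must be one of {LAYER_TYPES}")


@dataclass
class ChiPrediction:
    """Network output: per-(residue, chi) bin logits and per-bin offsets.

    logits: (L, 4, B); offsets: (L, 4, B) in bin-width units within
    (-1/2, 1/2); chi_mask: (L, 4) marking the chi angles the residue type
    defines.
    """

    logits: np.ndarray
    offsets: np.ndarray
    chi_mask: np.ndarray

    def probabilities(self) -> np.ndarray:
        z = self.logits - self.logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


# -- message passing layers -------------------------------------------------

class MPNNLayer(nn.Module):
    """Residual mean-aggregated messages of [n_i | n_j | e_ij] through an MLP."""

    def __init__(self, cfg: PIPPackConfig, rng):
        h = cfg.hidden_dim
        self.mlp = nn.MLP(2 * h + cfg.edge_dim, h, h, cfg.mlp_depth, rng)

    def __call__(self, nodes, edges, graph: F.ResidueGraph):
        L, k = graph.neighbor_idx.shape
        h = A.as_array(nodes).shape[-1]
        ni = A.broadcast_to(A.reshape(nodes, (L, 1, h)), (L, k, h))
        nj = A.take(nodes, graph.neighbor_idx)
        msg = self.mlp(A.concatenate([ni, nj, edges], axis=-1))
        return A.add(nodes, _masked_mean_over_edges(msg, graph.edge_mask))


class IPMPLayer(nn.Module):
    """Invariant point message passing.

    Each node emits learnable points in its local backbone frame; messages
    concatenate both node states, the edge state and five invariant
    geometric components of those points (see :meth:`components`), then pass
    through an MLP and are mean-aggregated with a residual update.
    """

    def __init__(self, cfg: PIPPackConfig, rng):
        h, p = cfg.hidden_dim, cfg.n_points
        self.n_points = p
        self.points_fn = nn.Linear(h, 3 * p, rng)
        d_geo = p * (3 + 1 + 3 + 1 + 1)
        self.mlp = nn.MLP(2 * h + cfg.edge_dim + d_geo, h, h, cfg.mlp_depth, rng)

    def components(self, points, graph: F.ResidueGraph):
        """The five invariant geometric message components, per edge.

        points: (L, n_points, 3) in each node's local frame.  Returns a
        (L, k, 9 * n_points) concatenation of: the receiver's own points;
        their squared norms; the sender's points mapped into the receiver's
        frame; the squared norms of those; and the squared global-frame
        distances between receiver and sender points.
        """
        L, k = graph.neighbor_idx.shape
        p = self.n_points
        rot = graph.frames.rotation            # (L, 3, 3), constant
        trans = graph.frames.translation       # (L, 3)
        nbr = graph.neighbor_idx

        pj = A.take(points, nbr)               # (L, k, p, 3)
        rot_j_t = np.swapaxes(rot[nbr], -1, -2)
        glob_pj = A.add(A.matmul(pj, rot_j_t), trans[nbr][:, :, None, :])
        local_pj = A.matmul(A.sub(glob_pj, trans[:, None, None, :]),
                            rot[:, None, :, :])

        glob_pi = A.add(A.matmul(points, np.swapaxes(rot, -1, -2)),
                        trans[:, None, :])     # (L, p, 3)

        c1 = A.broadcast_to(A.reshape(points, (L, 1, p, 3)), (L, k, p, 3))
        c2 = A.sum_(A.mul(c1, c1), axis=-1)
        c3 = local_pj
        c4 = A.sum_(A.mul(c3, c3), axis=-1)
        diff = A.sub(A.broadcast_to(A.reshape(glob_pi, (L, 1, p, 3)),
                                    (L, k, p, 3)), glob_pj)
        c5 = A.sum_(A.mul(diff, diff), axis=-1)
        return A.concatenate([
            A.reshape(c1, (L, k, 3 * p)), c2,
            A.reshape(c3, (L, k, 3 * p)), c4, c5,
        ], axis=-1)

    def message(self, n_i, t_i: RigidTransform, n_j, t_j: RigidTransform, e_ji):
        """Single-pair message j -> i (reference path used by tests and docs)."""
        graph = F.ResidueGraph(
            node_features=np.zeros((2, 1)), edge_features=np.zeros((2, 1, 1)),
            neighbor_idx=np.array([[1], [0]]),
            edge_mask=np.ones((2, 1), dtype=bool),
            frames=RigidTransform(
                np.stack([t_i.rotation, t_j.rotation]),
                np.stack([t_i.translation, t_j.translation])),
        )
        nodes = A.stack([n_i, n_j], axis=0)
        points = A.reshape(self.points_fn(nodes), (2, self.n_points, 3))
        geo_i = A.take(self.components(points, graph), (0, 0))  # edge j -> i
        m_in = A.concatenate([n_i, n_j, e_ji, geo_i], axis=-1)
        return self.mlp(m_in)

    def __call__(self, nodes, edges, graph: F.ResidueGraph):
        L, k = graph.neighbor_idx.shape
        h = A.as_array(nodes).shape[-1]
        points = A.reshape(self.points_fn(nodes), (L, self.n_points, 3))
        geo = self.components(points, graph)
        ni = A.broadcast_to(A.reshape(nodes, (L, 1, h)), (L, k, h))
        nj = A.take(nodes, graph.neighbor_idx)
        msg = self.mlp(A.concatenate([ni, nj, edges, geo], axis=-1))
        return A.add(nodes, _masked_mean_over_edges(msg, graph.edge_mask))


class IPALayer(nn.Module):
    """Neighborhood-restricted invariant point attention.

    The attention logits combine scalar query-key products, a learned edge
    bias, and squared distances between query and key points placed in the
    global frame; outputs gather attended scalar values, attended edges and
    attended value points expressed back in the receiver's local frame.
    """

    def __init__(self, cfg: PIPPackConfig, rng):
        h = cfg.hidden_dim
        self.heads = cfg.ipa_heads
        self.channels = cfg.ipa_channels
        self.n_qp = cfg.ipa_query_points
        self.n_vp = cfg.ipa_value_points
        hc = self.heads * self.channels
        self.to_q = nn.Linear(h, hc, rng, bias=False)
        self.to_k = nn.Linear(h, hc, rng, bias=False)
        self.to_v = nn.Linear(h, hc, rng, bias=False)
        self.to_qp = nn.Linear(h, self.heads * self.n_qp * 3, rng, bias=False)
        self.to_kp = nn.Linear(h, self.heads * self.n_qp * 3, rng, bias=False)
        self.to_vp = nn.Linear(h, self.heads * self.n_vp * 3, rng, bias=False)
        self.edge_bias = nn.Linear(cfg.edge_dim, self.heads, rng, bias=False)
        self.gamma = A.Tensor(np.zeros(self.heads), requires_grad=True)
        d_out = self.heads * (self.channels + cfg.edge_dim + 4 * self.n_vp)
        self.out = nn.Linear(d_out, h, rng, bias=False)

    def __call__(self, nodes, edges, graph: F.ResidueGraph):
        L, k = graph.neighbor_idx.shape
        H, c, nqp, nvp = self.heads, self.channels, self.n_qp, self.n_vp
        nbr = graph.neighbor_idx
        rot = graph.frames.rotation
        trans = graph.frames.translation
        rot_t = np.swapaxes(rot, -1, -2)

        q = A.reshape(self.to_q(nodes), (L, H, c))
        kk = A.take(A.reshape(self.to_k(nodes), (L, H, c)), nbr)   # (L,k,H,c)
        v = A.take(A.reshape(self.to_v(nodes), (L, H, c)), nbr)

        def to_global(lin, n_pts):
            pts = A.reshape(lin(nodes), (L, H, n_pts, 3))
            return A.add(A.matmul(pts, rot_t[:, None, :, :]),
                         trans[:, None, None, :])

        gq = to_global(self.to_qp, nqp)                 # (L,H,nqp,3)
        gk = A.take(to_global(self.to_kp, nqp), nbr)    # (L,k,H,nqp,3)
        gv = A.take(to_global(self.to_vp, nvp), nbr)

        logits_scalar = A.mul(
            A.sum_(A.mul(A.reshape(q, (L, 1, H, c)), kk), axis=-1),
            1.0 / np.sqrt(c))                            # (L,k,H)
        bias = self.edge_bias(edges)                     # (L,k,H)
        diff = A.sub(A.reshape(gq, (L, 1, H, nqp, 3)), gk)
        dist2 = A.sum_(A.mul(diff, diff), axis=(-1, -2))  # (L,k,H)
        w_c = np.sqrt(2.0 / (9.0 * nqp))
        gamma = A.softplus(self.gamma)
        logits = A.mul(
            A.sub(A.add(logits_scalar, bias),
                  A.mul(dist2, A.mul(gamma, w_c / 2.0))),
            np.sqrt(1.0 / 3.0))
        neg = np.where(graph.edge_mask, 0.0, -1e9)[:, :, None]
        attn = A.softmax(A.add(logits, neg), axis=1)
        attn = A.mul(attn, graph.edge_mask[:, :, None].astype(float))
        attn = A.div(attn, A.add(A.sum_(attn, axis=1, keepdims=True), 1e-9))

        o_scalar = A.sum_(A.mul(A.reshape(attn, (L, k, H, 1)), v), axis=1)
        o_edge = A.sum_(
            A.mul(A.reshape(attn, (L, k, H, 1)),
                  A.reshape(edges, (L, k, 1, edges.shape[-1]))), axis=1)
        o_pt_global = A.sum_(A.mul(A.reshape(attn, (L, k, H, 1, 1)), gv), axis=1)
        o_pt_local = A.matmul(A.sub(o_pt_global, trans[:, None, None, :]),
                              rot[:, None, :, :])        # (L,H,nvp,3)
        o_pt_norm = A.norm(o_pt_local, axis=-1, eps=1e-8)

        out = A.concatenate([
            A.reshape(o_scalar, (L, H * c)),
            A.reshape(o_edge, (L, H * edges.shape[-1])),
            A.reshape(o_pt_local, (L, H * nvp * 3)),
            A.reshape(o_pt_norm, (L, H * nvp)),
        ], axis=-1)
        # nodes without any neighbor receive no update at all
        has_edge = graph.edge_mask.any(axis=1).astype(float)[:, None]
        return A.add(nodes, self.out(A.mul(out, has_edge)))


def _masked_mean_over_edges(msg, edge_mask):
    count = np.clip(edge_mask.sum(axis=1, keepdims=True), 1, None).astype(float)
    masked = A.mul(msg, edge_mask[:, :, None].astype(float))
    return A.div(A.sum_(masked, axis=1), count)


def make_layer(cfg: PIPPackConfig, rng) -> nn.Module:
    return {"mpnn": MPNNLayer, "ipa": IPALayer, "ipmp": IPMPLayer}[cfg.layer_type](cfg, rng)


# -- the full network -------------------------------------------------------

class PIPPack(nn.Module):
    def __init__(self, cfg: PIPPackConfig, rng: np.random.Generator = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        h, e = cfg.hidden_dim, cfg.edge_dim
        self.node_proj = nn.Linear(F.NODE_DIM + F.RECYCLE_NODE_DIM, h, rng)
        self.edge_proj = nn.Linear(F.EDGE_DIM + F.RECYCLE_EDGE_DIM, e, rng)
        self.node_norm = nn.LayerNorm(h)
        self.edge_norm = nn.LayerNorm(e)
        self.layers = [make_layer(cfg, rng) for _ in range(cfg.n_layers)]
        self.inter_norms = [nn.LayerNorm(h) for _ in range(cfg.n_layers)]
        self.head = nn.MLP(h, h, 4 * cfg.n_bins * 2, cfg.mlp_depth, rng)

    def single_pass(self, graph: F.ResidueGraph):
        """One pass through the network; returns (logits, offsets) Tensors."""
        cfg = self.cfg
        L = graph.n_residues
        nodes = self.node_norm(self.node_proj(
            np.concatenate([graph.node_features, graph.recycle_node], axis=-1)))
        edges = self.edge_norm(self.edge_proj(
            np.concatenate([graph.edge_features, graph.recycle_edge], axis=-1)))
        for layer, norm in zip(self.layers, self.inter_norms):
            nodes = norm(layer(nodes, edges, graph))
        raw = A.reshape(self.head(nodes), (L, 4, 2 * cfg.n_bins))
        logits = A.take(raw, (slice(None), slice(None), slice(0, cfg.n_bins)))
        offsets = A.mul(A.tanh(A.take(
            raw, (slice(None), slice(None), slice(cfg.n_bins, 2 * cfg.n_bins)))), 0.5)
        return logits, offsets

    def forward_tensors(self, chain: ProteinChain, n_recycles: int = None,
                        graph: F.ResidueGraph = None):
        """Recycled forward returning final-pass (logits, offsets) Tensors.

        Runs ``n_recycles + 1`` passes; between passes the modes of the
        current prediction are decoded, side chains rebuilt with ideal
        geometry, and the recycling features recomputed.  No gradient flows
        through recycled features (they are recomputed outside the graph).
        """
        if n_recycles is None:
            n_recycles = self.cfg.n_recycles
        if graph is None:
            graph = F.featurize(chain, self.cfg.k_neighbors)
        chi_mask = R.CHI_MASK_BY_RESTYPE[chain.aatype]
        logits_t = offsets_t = None
        for cycle in range(n_recycles + 1):
            logits_t, offsets_t = self.single_pass(graph)
            if cycle < n_recycles:
                chi = binning.decode_mode_arrays(logits_t.data, offsets_t.data)
                chi = ChiAngles(chi * chi_mask, chi_mask)
                rebuilt = build_side_chains(chain, chi)
                graph.recycle_node, graph.recycle_edge = F.recycling_features(
                    rebuilt, chi, graph.neighbor_idx)
        return logits_t, offsets_t, graph

    def forward(self, chain: ProteinChain, n_recycles: int = None,
                graph: F.ResidueGraph = None) -> ChiPrediction:
        """Full prediction with recycling (see :meth:`forward_tensors`)."""
        logits_t, offsets_t, _ = self.forward_tensors(chain, n_recycles, graph)
        return ChiPrediction(logits_t.data, offsets_t.data,
                             R.CHI_MASK_BY_RESTYPE[chain.aatype])


def ensemble_logits(predictions: list[ChiPrediction]) -> ChiPrediction:
    """Average logits (and offsets) across models before the softmax."""
    if not predictions:
        raise ValueError("ensemble of zero predictions")
    logits = np.mean([p.logits for p in predictions], axis=0)
    offsets = np.mean([p.offsets for p in predictions], axis=0)
    return ChiPrediction(logits, offsets, predictions[0].chi_mask)


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model: PIPPack, path) -> None:
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.cfg)}
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path) -> PIPPack:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
    cfg = PIPPackConfig(**meta["config"])
    model = PIPPack(cfg, np.random.default_rng(0))
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
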