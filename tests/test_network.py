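"""Message-passing layers, the chi head, recycling and ensembling."""

import numpy as np
import pytest

from conftest import tiny_config
from pippack import features as F
from pippack import ops as A
from pippack.fixtures import FixtureSpec, make_backbone
from pippack.geometry import RigidTransform, random_rigid_transform
from pippack.model import (ChiPrediction, IPALayer, IPMPLayer, MPNNLayer,
                           PIPPack, ensemble_logits, load_checkpoint,
                           make_layer, save_checkpoint)


@pytest.fixture
def graph_and_nodes():
    chain = make_backbone(FixtureSpec(length=7, motif="coil", seed=21))
    graph = F.featurize(chain, k=4)
    rng = np.random.default_rng(0)
    nodes = rng.standard_normal((7, 16))
    edges = rng.standard_normal((7, 4, 16))
    return chain, graph, nodes, edges


def _zero_weights(module):
    for p in module.parameters():
        p.data[:] = 0.0


@pytest.mark.parametrize("layer_type", ["mpnn", "ipmp"])
def test_residual_layers_with_zero_mlp_are_identity(layer_type, graph_and_nodes):
    _, graph, nodes, edges = graph_and_nodes
    layer = make_layer(tiny_config(layer_type), np.random.default_rng(1))
    _zero_weights(layer.mlp)
    out = layer(nodes, edges, graph)
    np.testing.assert_allclose(A.as_array(out), nodes, atol=1e-12)


def test_mpnn_single_neighbor_mean_is_the_message(graph_and_nodes):
    _, graph, nodes, edges = graph_and_nodes
    layer = MPNNLayer(tiny_config("mpnn"), np.random.default_rng(2))
    single = graph.edge_mask.copy()
    single[:, 1:] = False
    graph.edge_mask = single
    out = A.as_array(layer(nodes, edges, graph))
    j = graph.neighbor_idx[:, 0]
    msg_in = np.concatenate([nodes, nodes[j], edges[:, 0]], axis=-1)
    msg = A.as_array(layer.mlp(msg_in))
    np.testing.assert_allclose(out, nodes + msg, atol=1e-9)


def test_mpnn_matches_loop_reference(graph_and_nodes):
    _, graph, nodes, edges = graph_and_nodes
    layer = MPNNLayer(tiny_config("mpnn"), np.random.default_rng(3))
    out = A.as_array(layer(nodes, edges, graph))
    for i in range(nodes.shape[0]):
        msgs = []
        for slot, j in enumerate(graph.neighbor_idx[i]):
            if not graph.edge_mask[i, slot]:
                continue
            m_in = np.concatenate([nodes[i], nodes[j], edges[i, slot]])
            msgs.append(A.as_array(layer.mlp(m_in)))
        expect = nodes[i] + np.mean(msgs, axis=0)
        np.testing.assert_allclose(out[i], expect, atol=1e-9)


def test_ipmp_matches_loop_reference(graph_and_nodes):
    _, graph, nodes, edges = graph_and_nodes
    layer = IPMPLayer(tiny_config("ipmp"), np.random.default_rng(4))
    out = A.as_array(layer(nodes, edges, graph))
    frames = graph.frames
    for i in range(nodes.shape[0]):
        msgs = []
        for slot, j in enumerate(graph.neighbor_idx[i]):
            if not graph.edge_mask[i, slot]:
                continue
            m = layer.message(nodes[i], frames[int(i)], nodes[j],
                              frames[int(j)], edges[i, slot])
            msgs.append(A.as_array(m))
        expect = nodes[i] + np.mean(msgs, axis=0)
        np.testing.assert_allclose(out[i], expect, atol=1e-8)


def test_ipmp_message_identity_frames_components():
    layer = IPMPLayer(tiny_config("ipmp"), np.random.default_rng(5))
    rng = np.random.default_rng(6)
    n_i, n_j = rng.standard_normal((2, 16))
    points = A.as_array(layer.points_fn(np.stack([n_i, n_j])))
    p_i = points[0].reshape(-1, 3)
    p_j = points[1].reshape(-1, 3)
    graph = F.ResidueGraph(
        node_features=np.zeros((2, 1)), edge_features=np.zeros((2, 1, 1)),
        neighbor_idx=np.array([[1], [0]]), edge_mask=np.ones((2, 1), dtype=bool),
        frames=RigidTransform.identity((2,)))
    geo = A.as_array(layer.components(
        A.as_array(layer.points_fn(np.stack([n_i, n_j]))).reshape(2, -1, 3),
        graph))[0, 0]
    p = layer.n_points
    c1, c2 = geo[:3 * p].reshape(p, 3), geo[3 * p:4 * p]
    c3 = geo[4 * p:7 * p].reshape(p, 3)
    c5 = geo[8 * p:]
    np.testing.assert_allclose(c1, p_i, atol=1e-12)
    np.testing.assert_allclose(c2, (p_i ** 2).sum(-1), atol=1e-12)
    np.testing.assert_allclose(c3, p_j, atol=1e-12)  # identity frames
    np.testing.assert_allclose(c5, ((p_i - p_j) ** 2).sum(-1), atol=1e-12)


def test_ipmp_message_invariant_under_shared_rigid_motion():
    layer = IPMPLayer(tiny_config("ipmp"), np.random.default_rng(7))
    rng = np.random.default_rng(8)
    n_i, n_j = rng.standard_normal((2, 16))
    e = rng.standard_normal(16)
    t_i = random_rigid_transform(rng)
    t_j = random_rigid_transform(rng)
    base = A.as_array(layer.message(n_i, t_i, n_j, t_j, e))
    for _ in range(3):
        g = random_rigid_transform(rng)
        moved = A.as_array(layer.message(n_i, g.compose(t_i), n_j,
                                         g.compose(t_j), e))
        assert np.abs(moved - base).max() < 1e-9


def test_zero_points_zero_components():
    layer = IPMPLayer(tiny_config("ipmp"), np.random.default_rng(9))
    _zero_weights(layer.points_fn)
    graph = F.ResidueGraph(
        node_features=np.zeros((2, 1)), edge_features=np.zeros((2, 1, 1)),
        neighbor_idx=np.array([[1], [0]]), edge_mask=np.ones((2, 1), dtype=bool),
        frames=RigidTransform.identity((2,)))
    points = np.zeros((2, layer.n_points, 3))
    geo = A.as_array(layer.components(points, graph))
    assert np.abs(geo).max() == 0.0


def test_ipa_invariant_and_matches_loop_reference(graph_and_nodes):
    _, graph, nodes, edges = graph_and_nodes
    cfg = tiny_config("ipa")
    layer = IPALayer(cfg, np.random.default_rng(10))
    out = A.as_array(layer(nodes, edges, graph))

    # invariance under a global rigid motion of the frames
    rng = np.random.default_rng(11)
    g = random_rigid_transform(rng)
    moved = F.ResidueGraph(
        node_features=graph.node_features, edge_features=graph.edge_features,
        neighbor_idx=graph.neighbor_idx, edge_mask=graph.edge_mask,
        frames=g.compose(graph.frames))
    out_moved = A.as_array(layer(nodes, edges, moved))
    assert np.abs(out - out_moved).max() < 1e-5

    # loop reference over each node's neighborhood
    H, c, nqp, nvp = layer.heads, layer.channels, layer.n_qp, layer.n_vp
    q = A.as_array(layer.to_q(nodes)).reshape(-1, H, c)
    k = A.as_array(layer.to_k(nodes)).reshape(-1, H, c)
    v = A.as_array(layer.to_v(nodes)).reshape(-1, H, c)
    qp = A.as_array(layer.to_qp(nodes)).reshape(-1, H, nqp, 3)
    kp = A.as_array(layer.to_kp(nodes)).reshape(-1, H, nqp, 3)
    vp = A.as_array(layer.to_vp(nodes)).reshape(-1, H, nvp, 3)
    gamma = np.logaddexp(0.0, layer.gamma.data)
    w_c = np.sqrt(2.0 / (9.0 * nqp))
    frames = graph.frames
    for i in range(nodes.shape[0]):
        ti = frames[int(i)]
        logit_rows, idx = [], []
        for slot, j in enumerate(graph.neighbor_idx[i]):
            if not graph.edge_mask[i, slot]:
                continue
            tj = frames[int(j)]
            scal = (q[i] * k[j]).sum(-1) / np.sqrt(c)
            bias = A.as_array(layer.edge_bias(edges[i, slot]))
            d2 = ((ti.apply(qp[i]) - tj.apply(kp[j])) ** 2).sum((-1, -2))
            logit_rows.append(np.sqrt(1 / 3) * (scal + bias - gamma * w_c / 2 * d2))
            idx.append((slot, j))
        logits = np.stack(logit_rows)
        a = np.exp(logits - logits.max(0))
        a /= a.sum(0)
        o_s = np.zeros((H, c))
        o_e = np.zeros((H, edges.shape[-1]))
        o_p = np.zeros((H, nvp, 3))
        for row, (slot, j) in enumerate(idx):
            tj = frames[int(j)]
            o_s += a[row][:, None] * v[j]
            o_e += a[row][:, None] * edges[i, slot]
            o_p += a[row][:, None, None] * tj.apply(vp[j])
        o_p_local = ti.inverse().apply(o_p)
        norm = np.sqrt((o_p_local ** 2).sum(-1) + 1e-8)
        feat = np.concatenate([o_s.ravel(), o_e.ravel(), o_p_local.ravel(),
                               norm.ravel()])
        expect = nodes[i] + A.as_array(layer.out(feat))
        np.testing.assert_allclose(out[i], expect, atol=1e-6)


def test_ipa_no_neighbors_is_identity(graph_and_nodes):
    _, graph, nodes, edges = graph_and_nodes
    layer = IPALayer(tiny_config("ipa"), np.random.default_rng(12))
    graph.edge_mask = np.zeros_like(graph.edge_mask)
    out = A.as_array(layer(nodes, edges, graph))
    np.testing.assert_allclose(out, nodes, atol=1e-9)


def test_chi_head_contract():
    chain = make_backbone(FixtureSpec(length=6, motif="coil", seed=30))
    model = PIPPack(tiny_config(), np.random.default_rng(13))
    pred = model.forward(chain, 0)
    assert pred.logits.shape == (6, 4, 72)
    assert pred.offsets.shape == (6, 4, 72)
    p = pred.probabilities()
    np.testing.assert_allclose(p.sum(-1), 1.0, atol=1e-6)
    assert (pred.offsets > -0.5).all() and (pred.offsets < 0.5).all()


def test_recycle_zero_equals_single_pass():
    chain = make_backbone(FixtureSpec(length=6, motif="coil", seed=31))
    model = PIPPack(tiny_config(), np.random.default_rng(14))
    graph = F.featurize(chain, model.cfg.k_neighbors)
    logits, offsets = model.single_pass(graph)
    pred = model.forward(chain, 0)
    np.testing.assert_array_equal(pred.logits, logits.data)
    np.testing.assert_array_equal(pred.offsets, offsets.data)


def test_end_to_end_invariance_with_recycling():
    chain = make_backbone(FixtureSpec(length=8, motif="coil", seed=32))
    model = PIPPack(tiny_config(), np.random.default_rng(15))
    g = random_rigid_transform(np.random.default_rng(16))
    p1 = model.forward(chain, 2)
    p2 = model.forward(chain.transformed(g), 2)
    assert np.abs(p1.logits - p2.logits).max() < 1e-4


def test_layer_types_are_drop_in_interchangeable():
    chain = make_backbone(FixtureSpec(length=6, motif="coil", seed=33))
    for lt in ("mpnn", "ipa", "ipmp"):
        model = PIPPack(tiny_config(lt), np.random.default_rng(17))
        pred = model.forward(chain, 1)
        assert pred.logits.shape == (6, 4, 72)
        assert np.isfinite(pred.logits).all()


def test_ensemble_mean_and_identity():
    rng = np.random.default_rng(18)
    mask = np.ones((2, 4), dtype=bool)
    a = ChiPrediction(rng.standard_normal((2, 4, 72)),
                      rng.standard_normal((2, 4, 72)) * 0.4, mask)
    assert ensemble_logits([a]).logits is not None
    np.testing.assert_array_equal(ensemble_logits([a]).logits, a.logits)
    same = ensemble_logits([a, a, a])
    np.testing.assert_allclose(same.logits, a.logits)
    with pytest.raises(ValueError):
        ensemble_logits([])


def test_logit_averaging_differs_from_probability_averaging():
    mask = np.ones((1, 4), dtype=bool)
    l1 = np.zeros((1, 4, 72))
    l2 = np.zeros((1, 4, 72))
    l1[..., 0], l2[..., 1] = 10.0, 10.0
    off = np.zeros((1, 4, 72))
    mean_logit_probs = ensemble_logits(
        [ChiPrediction(l1, off, mask), ChiPrediction(l2, off, mask)]
    ).probabilities()
    p1 = ChiPrediction(l1, off, mask).probabilities()
    p2 = ChiPrediction(l2, off, mask).probabilities()
    mean_probs = (p1 + p2) / 2
    assert np.abs(mean_logit_probs - mean_probs).max() > 0.05


def test_checkpoint_roundtrip_and_dimension_guard(tmp_path):
    chain = make_backbone(FixtureSpec(length=6, motif="coil", seed=34))
    model = PIPPack(tiny_config(), np.random.default_rng(19))
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    np.testing.assert_array_equal(loaded.forward(chain, 0).logits,
                                  model.forward(chain, 0).logits)
    other = PIPPack(tiny_config(hidden_dim=24), np.random.default_rng(20))
    with pytest.raises(ValueError, match="mismatch"):
        other.load_state_dict(model.state_dict())
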