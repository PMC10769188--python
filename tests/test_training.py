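"""Losses, discretization, Gumbel-Softmax, schedules and the fit loop."""

import io

import numpy as np
import pytest

from conftest import tiny_config
from pippack import binning
from pippack import features as F
from pippack import ops as A
from pippack.clash import clash_loss
from pippack.fixtures import FixtureSpec, make_backbone, make_chain, \
    make_clash_fixture, clash_fixture_prediction
from pippack.inference import strip_side_chains
from pippack.model import PIPPack
from pippack.structure import ChiAngles, build_side_chains, extract_chi
from pippack.training import (ChiTargets, TrainConfig, chain_targets, chi_loss,
                              chi_perplexity, discretize_chi, finetune_loss,
                              gumbel_chi_sample, gumbel_softmax, lr_schedule,
                              random_crop, fit, load_train_config,
                              GUMBEL_TEMPERATURE, FINETUNE_LR)


def test_discretize_boundaries_and_roundtrip():
    mask = np.ones((1, 4), dtype=bool)
    # lower domain boundary lands in bin 0 at offset -1/2
    t = discretize_chi(ChiAngles(np.full((1, 4), -np.pi), mask))
    assert (t.bin_index == 0).all()
    np.testing.assert_allclose(t.offset_target, -0.5)
    # a bin center has offset 0
    center = binning.bin_centers()[40]
    t = discretize_chi(ChiAngles(np.full((1, 4), center), mask))
    assert (t.bin_index == 40).all()
    np.testing.assert_allclose(t.offset_target, 0.0, atol=1e-12)
    # exact roundtrip on random angles
    rng = np.random.default_rng(0)
    chi = rng.uniform(-np.pi, np.pi, (250, 4))
    t = discretize_chi(ChiAngles(chi, np.ones((250, 4), dtype=bool)))
    back = binning.undiscretize(t.bin_index, t.offset_target)
    assert np.abs(back - chi).max() < 1e-9


def test_chi_loss_perfect_and_uniform():
    L, B = 3, 72
    mask = np.ones((L, 4), dtype=bool)
    targets = ChiTargets(np.full((L, 4), 7), np.zeros((L, 4)), mask)
    perfect = np.full((L, 4, B), -1e3)
    perfect[:, :, 7] = 1e3
    offsets = np.zeros((L, 4, B))
    total, ce, off = chi_loss(perfect, offsets, targets)
    assert float(A.as_array(total)) == pytest.approx(0.0, abs=1e-9)
    uniform = np.zeros((L, 4, B))
    _, ce, _ = chi_loss(uniform, offsets, targets)
    assert float(A.as_array(ce)) == pytest.approx(np.log(72))


def test_chi_loss_matches_loop_reference():
    rng = np.random.default_rng(1)
    L, B = 3, 72
    logits = rng.standard_normal((L, 4, B))
    offsets = rng.uniform(-0.5, 0.5, (L, 4, B))
    mask = rng.random((L, 4)) > 0.3
    targets = ChiTargets(rng.integers(0, B, (L, 4)),
                         rng.uniform(-0.5, 0.5, (L, 4)), mask)
    total, ce, off = chi_loss(logits, offsets, targets, offset_weight=1.0)
    ces, offs = [], []
    for i in range(L):
        for k in range(4):
            if not mask[i, k]:
                continue
            z = logits[i, k] - logits[i, k].max()
            logp = z - np.log(np.exp(z).sum())
            ces.append(-logp[targets.bin_index[i, k]])
            offs.append((offsets[i, k, targets.bin_index[i, k]]
                         - targets.offset_target[i, k]) ** 2)
    assert float(A.as_array(ce)) == pytest.approx(np.mean(ces))
    assert float(A.as_array(off)) == pytest.approx(np.mean(offs))
    assert float(A.as_array(total)) == pytest.approx(np.mean(ces) + np.mean(offs))


def test_perplexity_identities():
    L, B = 4, 72
    mask = np.ones((L, 4), dtype=bool)
    targets = ChiTargets(np.zeros((L, 4), dtype=int), np.zeros((L, 4)), mask)
    assert chi_perplexity(np.zeros((L, 4, B)), targets) == pytest.approx(72.0)
    sharp = np.full((L, 4, B), -1e3)
    sharp[:, :, 0] = 1e3
    assert chi_perplexity(sharp, targets) == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    logits = rng.standard_normal((L, 4, B))
    _, ce, _ = chi_loss(logits, np.zeros((L, 4, B)), targets)
    assert chi_perplexity(logits, targets) == pytest.approx(
        np.exp(float(A.as_array(ce))))


def test_gumbel_defaults_and_determinism():
    assert GUMBEL_TEMPERATURE == 1.0
    logits = np.array([[1.0, 0.0, -1.0]])
    s1 = gumbel_softmax(logits, rng=np.random.default_rng(3))
    s2 = gumbel_softmax(logits, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(s1.hard_index, s2.hard_index)
    np.testing.assert_allclose(A.as_array(s1.soft).sum(-1), 1.0)
    with pytest.raises(ValueError):
        gumbel_softmax(logits, temperature=0.0)


def test_gumbel_hard_sample_tracks_dominant_logit():
    logits = np.tile(np.array([10.0, -10.0, -10.0]), (10_000, 1))
    s = gumbel_softmax(logits, rng=np.random.default_rng(4))
    assert np.mean(s.hard_index == 0) >= 0.999


def test_clash_loss_hand_calculation():
    """Two carbons (r = 1.7 A each) at 3.0 A give penalty (3.4 - 3.0)^2 = 0.16."""
    from pippack.structure import ProteinChain
    one, _ = make_chain(FixtureSpec(length=1, sequence="A", seed=0))
    r0 = one.atom_coords[0]
    ca, cb = r0[1], r0[4]
    u = (cb - ca) / np.linalg.norm(cb - ca)
    p = cb + 1.5 * u
    coords = np.zeros((3, 14, 3))
    mask = np.zeros((3, 14), dtype=bool)
    coords[0], mask[0, :5] = r0, True
    coords[1, :4], mask[1, :4] = r0[:4] + 50.0, True   # remote glycine spacer
    coords[2], mask[2, :5] = 2 * p - r0, True          # CB at 3.0 A from CB(0)
    chain = ProteinChain("AGA", coords, mask)
    assert np.linalg.norm(coords[2, 4] - coords[0, 4]) == pytest.approx(3.0)
    assert clash_loss(chain) == pytest.approx(0.16, abs=1e-9)
    # pulling the pair beyond the radius sum removes the penalty
    coords[2] += 0.5 * u
    apart = ProteinChain("AGA", coords, mask)
    assert clash_loss(apart) == pytest.approx(0.0)


def test_clash_loss_matches_brute_force_loop():
    from pippack.clash import candidate_pairs
    chain = make_clash_fixture(seed=1)
    loss = clash_loss(chain)
    pairs, rsum, res_idx, slot_idx = candidate_pairs(chain)
    coords = chain.atom_coords[res_idx, slot_idx]
    expect = 0.0
    for (a, b), r in zip(pairs, rsum):
        d = np.linalg.norm(coords[a] - coords[b])
        expect += max(0.0, r - d) ** 2
    assert loss == pytest.approx(expect, rel=1e-9)
    assert loss > 0.0


def test_proline_closure_loss_cases():
    from pippack.clash import proline_closure_loss
    from pippack.fixtures import proline_closing_chi
    bb = make_backbone(FixtureSpec(length=3, sequence="APG", seed=0))
    chi_mask = np.zeros((3, 4), dtype=bool)
    chi_mask[1, :2] = True
    chi = np.zeros((3, 4))
    chi[1, :2] = proline_closing_chi()
    closed = build_side_chains(bb, ChiAngles(chi, chi_mask))
    assert proline_closure_loss(closed) < 1e-3
    chi[1, 0] += np.deg2rad(60)
    broken = build_side_chains(bb, ChiAngles(chi, chi_mask))
    assert proline_closure_loss(broken) > 0.1
    no_pro, _ = make_chain(FixtureSpec(length=3, sequence="AVL", seed=0))
    assert proline_closure_loss(no_pro) == 0.0


def test_gumbel_finetune_gradient_flow():
    """Coordinate losses reach the logits through the hard sample; they are
    silent when the sampled structure is clash-free."""
    chain = make_clash_fixture(seed=0)
    bb = strip_side_chains(chain)
    chi = extract_chi(chain)
    targets = chain_targets(chain)
    n_bins = binning.N_BINS
    idx, off = binning.discretize(chi.chi)
    logits = A.Tensor(np.zeros((len(chain), 4, n_bins)), requires_grad=True)
    base = np.zeros((len(chain), 4, n_bins))
    np.put_along_axis(base, idx[..., None], 25.0, axis=-1)
    logits.data += base  # concentrated on the clashing rotamer
    offsets = np.zeros((len(chain), 4, n_bins))
    np.put_along_axis(offsets, idx[..., None], off[..., None], axis=-1)

    cfg = TrainConfig(ce_weight=0.0)
    total, parts = finetune_loss(logits, offsets, bb, targets, cfg,
                                 np.random.default_rng(5))
    assert parts["clash"] > 0
    total.backward()
    assert np.abs(logits.grad).max() > 0

    # an overlap-free chain gives zero coordinate loss and zero gradient
    free, _ = make_chain(FixtureSpec(length=4, sequence="AGGA", seed=6))
    bb2 = strip_side_chains(free)
    logits2 = A.Tensor(np.zeros((4, 4, n_bins)), requires_grad=True)
    offsets2 = np.zeros((4, 4, n_bins))
    total2, parts2 = finetune_loss(logits2, offsets2, bb2,
                                   chain_targets(free), cfg,
                                   np.random.default_rng(7))
    assert parts2["clash"] == pytest.approx(0.0)
    assert parts2["proline"] == pytest.approx(0.0)
    total2.backward()
    assert np.abs(logits2.grad).max() == pytest.approx(0.0)


def test_lr_schedule_shape():
    warmup, d = 4000, 128
    peak = lr_schedule(warmup, warmup, d)
    assert peak == pytest.approx(d ** -0.5 * warmup ** -0.5)
    assert lr_schedule(warmup - 1, warmup, d) < peak
    values = [lr_schedule(s, warmup, d) for s in range(warmup, warmup * 4, 500)]
    assert all(a >= b for a, b in zip(values, values[1:]))
    assert lr_schedule(10, warmup, d, finetune=True) == FINETUNE_LR == 1e-8


def test_train_config_defaults_and_yaml(tmp_path):
    cfg = TrainConfig()
    assert cfg.crop_size == 512 and cfg.batch_size == 32
    path = tmp_path / "train.yaml"
    path.write_text("crop_size: 64\nbatch_size: 4\nseed: 9\n")
    loaded = load_train_config(path)
    assert (loaded.crop_size, loaded.batch_size, loaded.seed) == (64, 4, 9)


def test_random_crop_contract():
    chain = make_backbone(FixtureSpec(length=30, motif="coil", seed=8))
    rng = np.random.default_rng(0)
    assert random_crop(chain, 512, rng) is chain  # no-op below the crop size
    cropped = random_crop(chain, 10, rng)
    assert len(cropped) == 10
    assert cropped.sequence in chain.sequence


def test_bfactor_flag_masks_training_targets():
    chain, _ = make_chain(FixtureSpec(length=4, sequence="LLLL", seed=9))
    chain.b_factors[1, 6] = 80.0  # CD1 of residue 1
    targets = chain_targets(chain, bfactor_cutoff=40.0)
    assert targets.chi_mask[0].sum() == 2
    assert targets.chi_mask[1, 0] and not targets.chi_mask[1, 1]


def test_fit_reduces_validation_perplexity():
    chains = [make_chain(FixtureSpec(length=10, motif="coil",
                                     chi_mode="random", seed=s))[0]
              for s in range(2)]
    model = PIPPack(tiny_config(hidden_dim=24, edge_dim=24),
                    np.random.default_rng(21))
    log = io.StringIO()
    cfg = TrainConfig(batch_size=2, max_steps=60, eval_interval=20,
                      warmup_steps=30, n_recycles=0, seed=0, patience=10)
    history = fit(model, chains, cfg=cfg, log_file=log)
    assert len(history["val_perplexity"]) == 3
    assert history["val_perplexity"][-1] < history["val_perplexity"][0]
    assert history["val_perplexity"][-1] < 72.0
    assert len(log.getvalue().strip().splitlines()) == 3
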