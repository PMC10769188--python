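"""Losses and the training loop.

The primary objective is classification of each chi angle into angular bins
(cross-entropy) plus a regression penalty on the within-bin offset at the
target bin.  Validation chi perplexity — exp of the masked mean negative
log-likelihood of the native bins — drives early stopping.  A finetuning
stage draws differentiable hard samples from the predicted distributions
with the Gumbel-Softmax trick and adds coordinate-level penalties: a vdW
clash loss and an unclosed-proline-ring loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import binning
from . import features as F
from . import ops as A
from . import residues as R
from .clash import clash_loss_from_positions, proline_closure_loss
from .model import PIPPack, PIPPackConfig
from .structure import ChiAngles, ProteinChain, extract_chi, place_side_chain_atoms

GUMBEL_TEMPERATURE = 1.0  # lambda of the Gumbel-Softmax sampler
FINETUNE_LR = 1e-8


@dataclass
class ChiTargets:
    """Discretized native chi angles: bin class, in-bin offset, validity mask."""

    bin_index: np.ndarray     # (L, 4) int in [0, B)
    offset_target: np.ndarray  # (L, 4) in bin widths, [-1/2, 1/2)
    chi_mask: np.ndarray      # (L, 4) bool


def discretize_chi(chi: ChiAngles, n_bins: int = binning.N_BINS) -> ChiTargets:
    idx, offset = binning.discretize(chi.chi, n_bins)
    return ChiTargets(idx, offset * chi.chi_mask, chi.chi_mask.copy())


@dataclass
class TrainConfig:
    """Training-loop settings; loadable from a YAML file."""

    crop_size: int = 512
    batch_size: int = 32
    warmup_steps: int = 4000
    lr_scale: float = 1.0
    max_steps: int = 100_000
    eval_interval: int = 1000
    patience: int = 10            # evaluations without improvement
    n_recycles: int = 3
    seed: int = 0
    offset_weight: float = 1.0
    finetune: bool = False
    finetune_lr: float = FINETUNE_LR
    clash_weight: float = 1.0
    proline_weight: float = 1.0
    ce_weight: float = 1.0
    bfactor_cutoff: float = None  # discard chi depending on B > cutoff when set
    model: dict = field(default_factory=dict)


def load_train_config(path) -> TrainConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return TrainConfig(**raw)


# -- losses -----------------------------------------------------------------

def _gather_target(x, targets: ChiTargets):
    L = targets.bin_index.shape[0]
    ii = np.repeat(np.arange(L)[:, None], 4, axis=1)
    kk = np.broadcast_to(np.arange(4), (L, 4))
    return A.take(x, (ii, kk, targets.bin_index))


def _masked_mean(x, mask):
    denom = max(float(mask.sum()), 1.0)
    return A.div(A.sum_(A.mul(x, mask.astype(float))), denom)


def chi_loss(logits, offsets, targets: ChiTargets, offset_weight: float = 1.0):
    """Masked-mean bin cross-entropy plus offset L2 at the target bin.

    Returns (total, cross_entropy, offset_term); works on Tensors during
    training and on plain arrays for logging.
    """
    logp = A.log_softmax(logits, axis=-1)
    ce = _masked_mean(A.mul(_gather_target(logp, targets), -1.0), targets.chi_mask)
    off_err = A.sub(_gather_target(offsets, targets), targets.offset_target)
    off = _masked_mean(A.mul(off_err, off_err), targets.chi_mask)
    total = A.add(ce, A.mul(off, offset_weight))
    return total, ce, off


def chi_perplexity(logits, targets: ChiTargets) -> float:
    """exp(masked mean NLL of the native bins); 1 is perfect, B is uniform."""
    logp = A.log_softmax(A.as_array(logits), axis=-1)
    nll = -_gather_target(logp, targets)
    return float(np.exp(A.as_array(_masked_mean(nll, targets.chi_mask))))


# -- Gumbel-Softmax sampling ------------------------------------------------

@dataclass
class GumbelSample:
    """A (near-)discrete differentiable categorical sample.

    ``soft`` holds the Gumbel-Softmax simplex weights; ``hard_index`` the
    argmax class; ``straight_through`` the one-hot forward value whose
    gradient is that of ``soft``.
    """

    soft: object              # (..., B) Tensor or ndarray
    hard_index: np.ndarray    # (...,) int
    straight_through: object  # (..., B)
    temperature: float


def gumbel_softmax(logits, temperature: float = GUMBEL_TEMPERATURE,
                   rng: np.random.Generator = None) -> GumbelSample:
    """Sample from softmax(logits) via iid Gumbel noise on the logits.

    The hard sample distribution equals softmax(logits) regardless of the
    temperature; the temperature only controls the softness of the
    relaxation that carries the gradient.
    """
    if temperature <= 0:
        raise ValueError("Gumbel-Softmax temperature must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    data = A.as_array(logits)
    noise = rng.gumbel(size=data.shape)
    soft = A.softmax(A.mul(A.add(logits, noise), 1.0 / temperature), axis=-1)
    soft_data = A.as_array(soft)
    hard_index = np.argmax(soft_data, axis=-1)
    onehot = np.zeros_like(soft_data)
    np.put_along_axis(onehot, hard_index[..., None], 1.0, axis=-1)
    if A.is_tensor(soft):
        straight = A.add(soft, A.Tensor(onehot - soft_data))
    else:
        straight = onehot
    return GumbelSample(soft, hard_index, straight, temperature)


def gumbel_chi_sample(logits, offsets, chi_mask, temperature: float,
                      rng: np.random.Generator):
    """Differentiable chi angles from a Gumbel-Softmax hard sample.

    chi = <straight-through one-hot, bin centers> + offset(sampled bin) * w.
    Gradients reach the logits through the relaxed sample and the offsets
    through the gather.
    """
    n_bins = A.as_array(logits).shape[-1]
    sample = gumbel_softmax(logits, temperature, rng)
    centers = binning.bin_centers(n_bins)
    w = binning.bin_width(n_bins)
    L = chi_mask.shape[0]
    ii = np.repeat(np.arange(L)[:, None], 4, axis=1)
    kk = np.broadcast_to(np.arange(4), (L, 4))
    off = A.take(offsets, (ii, kk, sample.hard_index))
    chi = A.add(A.sum_(A.mul(sample.straight_through, centers), axis=-1),
                A.mul(off, w))
    return A.mul(chi, chi_mask.astype(float)), sample


def finetune_loss(logits, offsets, chain: ProteinChain, targets: ChiTargets,
                  cfg: TrainConfig, rng: np.random.Generator):
    """Finetuning objective: CE + offset + clash + proline-closure terms.

    The coordinate terms act on side chains built from a Gumbel-Softmax
    sample of the predicted distributions, so their gradients flow back to
    the logits through the straight-through estimator and the ideal-geometry
    reconstruction.
    """
    ce_total, ce, off = chi_loss(logits, offsets, targets, cfg.offset_weight)
    chi_t, _ = gumbel_chi_sample(logits, offsets, targets.chi_mask,
                                 GUMBEL_TEMPERATURE, rng)
    placed = place_side_chain_atoms(chain, chi_t)
    built = _rebuild_numeric(chain, placed)
    clash = clash_loss_from_positions(built, placed)
    pro = proline_closure_loss(built, placed)
    total = A.add(A.mul(ce_total, cfg.ce_weight),
                  A.add(A.mul(clash, cfg.clash_weight),
                        A.mul(pro, cfg.proline_weight)))
    return total, {"ce": float(A.as_array(ce)), "offset": float(A.as_array(off)),
                   "clash": float(A.as_array(clash)),
                   "proline": float(A.as_array(pro))}


def _rebuild_numeric(chain: ProteinChain, placed: dict) -> ProteinChain:
    """Numeric chain whose coordinates agree with the placed side chains."""
    coords = chain.atom_coords.copy()
    mask = chain.atom_mask.copy()
    for (i, j), p in placed.items():
        coords[i, j] = A.as_array(p)
        mask[i, j] = True
    mask &= R.ATOM14_EXISTS[chain.aatype]
    coords[~mask] = 0.0
    return ProteinChain(chain.sequence, coords, mask, chain.b_factors,
                        chain.residue_ids, chain.chain_id)


# -- optimizer schedule -----------------------------------------------------

def lr_schedule(step: int, warmup: int, model_dim: int,
                finetune: bool = False, finetune_lr: float = FINETUNE_LR) -> float:
    """Inverse-square-root schedule with linear warmup; constant in finetuning."""
    if finetune:
        return finetune_lr
    step = max(int(step), 1)
    return model_dim ** -0.5 * min(step ** -0.5, step * warmup ** -1.5)


# -- training loop ----------------------------------------------------------

def chain_targets(chain: ProteinChain, n_bins: int = binning.N_BINS,
                  bfactor_cutoff: float = None) -> ChiTargets:
    """Native chi targets for a chain, optionally B-factor filtered."""
    chi = extract_chi(chain)
    targets = discretize_chi(chi, n_bins)
    if bfactor_cutoff is not None:
        from .evaluation import bfactor_chi_filter
        targets.chi_mask &= bfactor_chi_filter(chain, bfactor_cutoff)
    return targets


def random_crop(chain: ProteinChain, crop_size: int,
                rng: np.random.Generator) -> ProteinChain:
    """Random contiguous crop; a no-op for chains at or below the crop size."""
    L = len(chain)
    if L <= crop_size:
        return chain
    start = int(rng.integers(0, L - crop_size + 1))
    sl = slice(start, start + crop_size)
    return ProteinChain(chain.sequence[sl], chain.atom_coords[sl],
                        chain.atom_mask[sl], chain.b_factors[sl],
                        chain.residue_ids[sl], chain.chain_id)


def fit(model: PIPPack, train_chains: list, val_chains: list = None,
        cfg: TrainConfig = None, log_file=None) -> dict:
    """Train with Adam under the warmup schedule and perplexity early stopping.

    Returns a history dict with per-evaluation metrics.  Metrics are also
    written as line-delimited JSON to ``log_file`` when given.
    """
    from .nn import Adam

    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters())
    cache = {}

    def graph_and_targets(chain, idx):
        cropped = random_crop(chain, cfg.crop_size, rng)
        key = idx if cropped is chain else None
        if key is not None and key in cache:
            return cache[key]
        graph = F.featurize(cropped, model.cfg.k_neighbors)
        targets = chain_targets(cropped, model.cfg.n_bins, cfg.bfactor_cutoff)
        item = (cropped, graph, targets)
        if key is not None:
            cache[key] = item
        return item

    history = {"steps": [], "train_loss": [], "val_perplexity": []}
    best = np.inf
    stale = 0
    for step in range(1, cfg.max_steps + 1):
        batch_idx = rng.choice(len(train_chains),
                               size=min(cfg.batch_size, len(train_chains)),
                               replace=False)
        model.zero_grad()
        batch_loss = 0.0
        for idx in batch_idx:
            cropped, graph, targets = graph_and_targets(train_chains[idx], int(idx))
            logits, offsets, _ = model.forward_tensors(
                cropped, cfg.n_recycles, graph)
            if cfg.finetune:
                loss, _ = finetune_loss(logits, offsets, cropped, targets, cfg, rng)
            else:
                loss, _, _ = chi_loss(logits, offsets, targets, cfg.offset_weight)
            loss = A.mul(loss, 1.0 / len(batch_idx))
            loss.backward()
            batch_loss += float(loss.data)
        lr = cfg.lr_scale * lr_schedule(step, cfg.warmup_steps,
                                        model.cfg.hidden_dim,
                                        cfg.finetune, cfg.finetune_lr)
        opt.step(lr=lr)

        if step % cfg.eval_interval == 0 or step == cfg.max_steps:
            val = _validation_perplexity(model, val_chains or train_chains, cfg)
            history["steps"].append(step)
            history["train_loss"].append(batch_loss)
            history["val_perplexity"].append(val)
            if log_file is not None:
                log_file.write(json.dumps(
                    {"step": step, "lr": lr, "train_loss": batch_loss,
                     "val_perplexity": val}) + "\n")
            if val < best - 1e-6:
                best = val
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    return history


def _validation_perplexity(model: PIPPack, chains: list, cfg: TrainConfig) -> float:
    nlls, weights = [], []
    for chain in chains:
        pred = model.forward(chain, cfg.n_recycles)
        targets = chain_targets(chain, model.cfg.n_bins, cfg.bfactor_cutoff)
        ppl = chi_perplexity(pred.logits, targets)
        n = float(targets.chi_mask.sum())
        nlls.append(np.log(ppl) * n)
        weights.append(n)
    return float(np.exp(np.sum(nlls) / max(np.sum(weights), 1.0)))
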