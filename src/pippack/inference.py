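"""Decoding predictions into structures and post-processing.

The network outputs a categorical distribution over chi-angle bins per
(residue, chi).  Decoding takes the distribution mode (deterministic) or a
temperature-scaled categorical sample.  Because samples occasionally
produce steric overlaps or unclosed proline rings, a Metropolis resampling
pass re-draws chi angles for offending residues against a quadratic
overlap/closure energy, gradually raising the sampling temperature to trade
probability mass for conformational diversity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import binning
from . import residues as R
from .clash import (clash_loss, find_clashing_residues, proline_cd_n_deviation,
                    proline_closure_loss, proline_indices)
from .model import ChiPrediction, PIPPack, ensemble_logits
from .structure import ChiAngles, ProteinChain, build_side_chains, extract_chi

PROLINE_CLOSURE_TOLERANCE = 0.3  # Angstrom deviation of Cdelta-N from ideal


@dataclass
class ResampleSchedule:
    """Temperature protocol for Metropolis chi resampling."""

    initial_temperature: float = 0.1
    temperature_ramp: float = 1.5   # multiplicative, per round
    max_rounds: int = 50
    proposals_per_round: int = 1    # proposals per flagged residue per round
    seed: int = 0

    def temperature(self, round_index: int) -> float:
        return self.initial_temperature * self.temperature_ramp ** round_index

    def __post_init__(self):
        if self.initial_temperature <= 0 or self.temperature_ramp < 1.0:
            raise ValueError("temperatures must be positive and non-decreasing")


def decode_mode(pred: ChiPrediction) -> ChiAngles:
    """Chi angles at the distribution mode (ties -> lowest bin index)."""
    chi = binning.decode_mode_arrays(pred.logits, pred.offsets)
    return ChiAngles(chi * pred.chi_mask, pred.chi_mask.copy())


def sample_chi(pred: ChiPrediction, temperature: float = 1.0,
               seed=0, residues=None) -> ChiAngles:
    """Categorical sample from softmax(logits / T) plus the sampled bin's offset.

    ``temperature`` 0 reduces to :func:`decode_mode`.  ``residues`` optionally
    restricts sampling to a subset (others keep the mode).  ``seed`` may be an
    integer or a Generator.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    mode = decode_mode(pred)
    if temperature == 0:
        return mode
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = np.arange(pred.logits.shape[0]) if residues is None \
        else np.asarray(list(residues), dtype=int)
    logits = pred.logits[rows] / temperature
    z = logits - logits.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(cdf.shape[:-1] + (1,))
    idx = (u > cdf).sum(axis=-1)
    off = np.take_along_axis(pred.offsets[rows], idx[..., None], axis=-1)[..., 0]
    chi = mode.chi.copy()
    chi[rows] = binning.undiscretize(idx, off, pred.logits.shape[-1])
    return ChiAngles(chi * pred.chi_mask, pred.chi_mask.copy())


def find_unclosed_prolines(chain: ProteinChain,
                           tolerance: float = PROLINE_CLOSURE_TOLERANCE) -> set:
    """Prolines whose Cdelta-N distance deviates from ideal by > tolerance."""
    idx = proline_indices(chain)
    dev = proline_cd_n_deviation(chain)
    return set(idx[dev > tolerance].tolist())


def _resample_energy(chain: ProteinChain, geometry) -> float:
    return clash_loss(chain, geometry) + proline_closure_loss(chain)


def resample_mcmc(chain: ProteinChain, pred: ChiPrediction,
                  schedule: ResampleSchedule = None,
                  geometry: R.IdealGeometry = R.IDEAL_GEOMETRY) -> ProteinChain:
    """Metropolis resampling of clashing and unclosed-proline residues.

    Each round flags offending residues, proposes fresh chi angles for them
    one residue at a time from the predicted distributions at the round's
    temperature, and accepts with probability min(1, exp(-dE/T)) against the
    quadratic overlap + proline-closure energy.  Residues that are never
    flagged keep their input chi angles untouched.
    """
    schedule = schedule or ResampleSchedule()
    rng = np.random.default_rng(schedule.seed)
    chi_cur = extract_chi(chain, geometry)
    current = chain
    energy = _resample_energy(current, geometry)
    for round_index in range(schedule.max_rounds):
        flagged = sorted(find_clashing_residues(current, geometry)
                         | find_unclosed_prolines(current))
        if not flagged:
            break
        temp = schedule.temperature(round_index)
        for res in flagged:
            for _ in range(schedule.proposals_per_round):
                proposal = sample_chi(pred, temp, rng, residues=[res])
                chi_new = ChiAngles(chi_cur.chi.copy(), chi_cur.chi_mask.copy())
                chi_new.chi[res] = proposal.chi[res]
                candidate = build_side_chains(chain, chi_new, geometry)
                e_new = _resample_energy(candidate, geometry)
                delta = e_new - energy
                if delta <= 0 or rng.random() < np.exp(-delta / temp):
                    chi_cur, current, energy = chi_new, candidate, e_new
    return current


def strip_side_chains(chain: ProteinChain) -> ProteinChain:
    """Keep backbone N/CA/C/O (and CB); drop all other side-chain atoms."""
    mask = chain.atom_mask.copy()
    mask[:, 5:] = False
    coords = chain.atom_coords.copy()
    coords[~mask] = 0.0
    b = chain.b_factors.copy()
    b[~mask] = 0.0
    return ProteinChain(chain.sequence, coords, mask, b,
                        chain.residue_ids.copy(), chain.chain_id)


def pack(chain: ProteinChain, models, n_recycles: int = None,
         mode: str = "mode", temperature: float = 1.0, seed: int = 0,
         resample_schedule: ResampleSchedule = None,
         geometry: R.IdealGeometry = R.IDEAL_GEOMETRY) -> ProteinChain:
    """Full packing protocol: featurize, predict, decode, build, post-process.

    Parameters
    ----------
    models:
        A single network or a list; several models are ensembled by
        averaging their logits before the softmax.
    mode:
        "mode" (deterministic argmax decode), "sample" (temperature
        sampling), or "resample" (mode decode followed by Metropolis
        resampling of clashing/unclosed residues).
    """
    if mode not in ("mode", "sample", "resample"):
        raise ValueError(f"unknown decode mode {mode!r}")
    if isinstance(models, PIPPack):
        models = [models]
    backbone = strip_side_chains(chain)
    if not backbone.atom_mask[:, :3].all():
        raise ValueError("packing requires complete N/CA/C backbone")
    preds = [m.forward(backbone, n_recycles) for m in models]
    pred = preds[0] if len(preds) == 1 else ensemble_logits(preds)
    if mode == "sample":
        chi = sample_chi(pred, temperature, seed)
    else:
        chi = decode_mode(pred)
    packed = build_side_chains(backbone, chi, geometry)
    if mode == "resample":
        schedule = resample_schedule or ResampleSchedule(seed=seed)
        packed = resample_mcmc(packed, pred, schedule, geometry)
    return packed
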