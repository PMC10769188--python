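"""Synthetic single-chain structures with known ground-truth chi angles.

Backbones are chained with ideal bond lengths and angles from per-residue
(phi, psi, omega) motifs; side chains are built from assigned chi angles
with the same ideal-geometry tables the rest of the package uses, so the
assigned angles are exactly recoverable.  These fixtures exercise every
geometric and learning code path without any structure downloads; they do
not emulate realistic packing statistics or rotamer-library frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from . import residues as R
from .clash import find_clashing_residues
from .geometry import place_atom
from .structure import ChiAngles, ProteinChain, build_side_chains, extract_chi

MOTIF_ANGLES_DEG = {
    "helix": (-57.0, -47.0, 180.0),
    "strand": (-120.0, 120.0, 180.0),
}

STAGGERED_CHI_DEG = (-60.0, 60.0, 180.0)

_BG = R.BACKBONE_GEOMETRY


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic chain (same spec+seed, same atoms)."""

    length: int
    sequence: str = None            # random draw when omitted
    motif: str = "helix"            # helix | strand | coil
    phi_psi_omega: tuple = None     # degrees, overrides the motif
    chi_mode: str = "staggered"     # staggered | random | fixed
    chi_values: np.ndarray = None   # radians, used when chi_mode == "fixed"
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _dihedral_plan(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """(L, 3) per-residue (phi, psi, omega) in radians."""
    if spec.phi_psi_omega is not None:
        base = np.deg2rad(np.asarray(spec.phi_psi_omega, dtype=float))
        return np.tile(base, (spec.length, 1))
    if spec.motif == "coil":
        angles = np.stack([
            rng.uniform(-np.pi, np.pi, spec.length),
            rng.uniform(-np.pi, np.pi, spec.length),
            np.full(spec.length, np.pi - 1e-9),
        ], axis=1)
        return angles
    phi, psi, omega = MOTIF_ANGLES_DEG[spec.motif]
    return np.tile(np.deg2rad([phi, psi, omega]), (spec.length, 1))


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(R.RESTYPES), size=length))


def make_backbone(spec: FixtureSpec) -> ProteinChain:
    """Ideal-geometry backbone (N, CA, C, O per residue) from the dihedral plan."""
    rng = spec.rng()
    seq = spec.sequence or _random_sequence(spec.length, rng)
    if len(seq) != spec.length:
        raise ValueError("sequence length disagrees with spec length")
    plan = _dihedral_plan(spec, rng)
    L = spec.length
    coords = np.zeros((L, R.MAX_ATOMS, 3))
    theta = np.deg2rad(_BG[("N", "CA", "C")])
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [_BG[("N", "CA")], 0.0, 0.0]
    coords[0, 2] = coords[0, 1] + _BG[("CA", "C")] * np.array(
        [-np.cos(theta), np.sin(theta), 0.0])
    for i in range(1, L):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        coords[i, 0] = place_atom(c_prev, ca_prev, n_prev, _BG[("C", "N")],
                                  np.deg2rad(_BG[("CA", "C", "N")]),
                                  plan[i - 1, 1])          # psi(i-1)
        coords[i, 1] = place_atom(coords[i, 0], c_prev, ca_prev, _BG[("N", "CA")],
                                  np.deg2rad(_BG[("C", "N", "CA")]),
                                  plan[i, 2])              # omega(i)
        coords[i, 2] = place_atom(coords[i, 1], coords[i, 0], c_prev,
                                  _BG[("CA", "C")],
                                  np.deg2rad(_BG[("N", "CA", "C")]),
                                  plan[i, 0])              # phi(i)
    for i in range(L):
        coords[i, 3] = place_atom(coords[i, 2], coords[i, 1], coords[i, 0],
                                  _BG[("C", "O")],
                                  np.deg2rad(_BG[("CA", "C", "O")]),
                                  plan[i, 1] + np.pi)      # O anti to psi
    mask = np.zeros((L, R.MAX_ATOMS), dtype=bool)
    mask[:, :4] = True
    return ProteinChain(seq, coords, mask)


@lru_cache(maxsize=1)
def proline_closing_chi() -> tuple:
    """(chi1, chi2) in radians that close the proline ring with ideal geometry.

    Found once by minimizing the Cdelta-N bond-length error on an ideal
    backbone from a standard down-pucker start.
    """
    spec = FixtureSpec(length=1, sequence="P")
    bb = make_backbone(spec)

    def closure_error(chi12):
        chi = np.zeros((1, 4))
        chi[0, :2] = chi12
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, :2] = True
        built = build_side_chains(bb, ChiAngles(chi, mask))
        cd = built.atom_coords[0, R.ATOM14_NAMES["PRO"].index("CD")]
        return (np.linalg.norm(cd - built.atom_coords[0, 0]) - R.PRO_CD_N_BOND) ** 2

    res = minimize(closure_error, x0=np.deg2rad([25.0, -35.0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-16})
    if res.fun > 1e-8:
        raise RuntimeError("proline ring-closure search failed")
    return tuple(float(x) for x in res.x)


def assign_rotamers(chain: ProteinChain, spec: FixtureSpec):
    """Draw ground-truth chi angles and build the side chains.

    Returns (chain with all heavy atoms, ChiAngles ground truth).  Staggered
    mode draws from {-60, 60, 180} degrees; prolines always receive the
    ring-closing pair.
    """
    rng = np.random.default_rng(spec.seed + 1)
    L = len(chain)
    chi_mask = R.CHI_MASK_BY_RESTYPE[chain.aatype].copy()
    if spec.chi_mode == "fixed":
        chi = np.asarray(spec.chi_values, dtype=float).reshape(L, 4).copy()
    elif spec.chi_mode == "random":
        chi = rng.uniform(-np.pi, np.pi, size=(L, 4))
    elif spec.chi_mode == "staggered":
        chi = np.deg2rad(rng.choice(STAGGERED_CHI_DEG, size=(L, 4)))
    else:
        raise ValueError(f"unknown chi_mode {spec.chi_mode!r}")
    pro = chain.aatype == R.RESTYPE3_ORDER["PRO"]
    if pro.any() and spec.chi_mode != "fixed":
        chi[pro, :2] = proline_closing_chi()
    chi = chi * chi_mask
    truth = ChiAngles(chi, chi_mask)
    return build_side_chains(chain, truth), truth


def make_chain(spec: FixtureSpec):
    """Backbone plus assigned rotamers in one call; returns (chain, chi truth)."""
    return assign_rotamers(make_backbone(spec), spec)


def make_clash_fixture(seed: int = 0, return_rotamers: bool = False):
    """A short helix where two leucines are built into a steric clash.

    The two leucines sit one helical turn apart; their chi angles are chosen
    (seed-dependently) from the staggered grid so that the built side chains
    overlap by more than 0.4 A, while at least one alternative staggered
    assignment is clash-free.  Both facts are verified at construction.

    Returns the clashing chain; with ``return_rotamers`` also the list of
    clash-free (chi_a, chi_b) alternatives and the two residue indices.
    """
    rng = np.random.default_rng(seed)
    seq = "AGLAALGA"  # LEU at indices 2 and 5, one helical turn apart
    positions = (2, 5)
    bb = make_backbone(FixtureSpec(length=len(seq), sequence=seq, motif="helix",
                                   seed=seed))
    grid = [np.deg2rad([c1, c2]) for c1 in STAGGERED_CHI_DEG
            for c2 in STAGGERED_CHI_DEG]
    chi_mask = R.CHI_MASK_BY_RESTYPE[bb.aatype].copy()

    clashing, clash_free = [], []
    for a in grid:
        for b in grid:
            chi = np.zeros((len(seq), 4))
            chi[positions[0], :2] = a
            chi[positions[1], :2] = b
            built = build_side_chains(bb, ChiAngles(chi * chi_mask, chi_mask))
            flagged = find_clashing_residues(built)
            if set(positions) <= flagged:
                clashing.append((a, b))
            elif not flagged:
                clash_free.append((a, b))
    if not clashing or not clash_free:
        raise RuntimeError("clash fixture construction failed: "
                           f"{len(clashing)} clashing / {len(clash_free)} free")
    pick = clashing[rng.integers(0, len(clashing))]
    chi = np.zeros((len(seq), 4))
    chi[positions[0], :2], chi[positions[1], :2] = pick
    chain = build_side_chains(bb, ChiAngles(chi * chi_mask, chi_mask))
    if return_rotamers:
        return chain, clash_free, positions
    return chain


def clash_fixture_prediction(chain: ProteinChain, concentration: float = 3.0):
    """A synthetic ChiPrediction over a clash fixture.

    Logits put most mass on each residue's currently built chi bin and
    spread the rest over the staggered alternatives, so Metropolis
    resampling has clash-free bins available to discover.
    """
    from . import binning
    from .model import ChiPrediction

    chi = extract_chi(chain)
    n_bins = binning.N_BINS
    logits = np.full((len(chain), 4, n_bins), -8.0)
    offsets = np.zeros((len(chain), 4, n_bins))
    cur_idx, cur_off = binning.discretize(chi.chi, n_bins)
    alt_idx, _ = binning.discretize(np.deg2rad(STAGGERED_CHI_DEG), n_bins)
    for i in range(len(chain)):
        for k in range(4):
            if not chi.chi_mask[i, k]:
                continue
            for b in alt_idx:
                logits[i, k, b] = 0.0
            logits[i, k, cur_idx[i, k]] = concentration
            offsets[i, k, cur_idx[i, k]] = cur_off[i, k]
    return ChiPrediction(logits, offsets, chi.chi_mask.copy())
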