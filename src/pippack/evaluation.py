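"""Side-chain packing evaluation metrics.

Rotamer recovery counts a residue as recovered when every defined chi angle
lies within a tolerance (20 degrees) of the native; per-residue RMSD
superposes each residue's four backbone atoms and scores the side-chain
heavy atoms including CB; chi MAE averages the periodic absolute error per
chi index.  Chemically indistinguishable terminal groups (PHE/TYR ring
flips, ASP/GLU carboxylates, ARG guanidinium relabeling) are scored under
their 180-degree symmetry by default, which can be disabled to match
conventions that ignore it.
"""

from __future__ import annotations

import numpy as np

from . import residues as R
from .clash import clashscore  # re-exported as part of the metric suite
from .geometry import kabsch, wrap_angle
from .structure import ChiAngles, ProteinChain

__all__ = [
    "rotamer_recovered", "chi_mae", "per_residue_rmsd", "clashscore",
    "centrality", "bfactor_chi_filter", "evaluate",
    "ROTAMER_TOLERANCE_DEG", "CORE_MIN_NEIGHBORS", "SURFACE_MAX_NEIGHBORS",
    "CENTRALITY_RADIUS", "BFACTOR_CUTOFF",
]

ROTAMER_TOLERANCE_DEG = 20.0
CORE_MIN_NEIGHBORS = 20
SURFACE_MAX_NEIGHBORS = 15
CENTRALITY_RADIUS = 10.0   # Angstrom, CB-CB
BFACTOR_CUTOFF = 40.0      # Angstrom^2


def chi_errors_deg(pred_chi: ChiAngles, native_chi: ChiAngles,
                   aatype: np.ndarray, use_symmetry: bool = True):
    """(L, 4) absolute chi errors in degrees plus the joint validity mask."""
    mask = pred_chi.chi_mask & native_chi.chi_mask
    diff = np.abs(wrap_angle(pred_chi.chi - native_chi.chi))
    if use_symmetry:
        sym = R.CHI_SYMMETRIC[aatype]
        flipped = np.abs(wrap_angle(pred_chi.chi - native_chi.chi + np.pi))
        diff = np.where(sym, np.minimum(diff, flipped), diff)
    return np.degrees(diff) * mask, mask


def rotamer_recovered(pred_chi: ChiAngles, native_chi: ChiAngles,
                      aatype: np.ndarray,
                      tol_deg: float = ROTAMER_TOLERANCE_DEG,
                      use_symmetry: bool = True):
    """Per-residue recovery flags and the has-chi mask.

    A rotamer is recovered iff *all* defined chi angles are within
    ``tol_deg`` of the native.  Residues without chi angles are excluded via
    the returned mask.
    """
    err, mask = chi_errors_deg(pred_chi, native_chi, aatype, use_symmetry)
    has_chi = mask.any(axis=1)
    ok = np.where(mask, err <= tol_deg, True).all(axis=1)
    return ok & has_chi, has_chi


def chi_mae(pred_chi: ChiAngles, native_chi: ChiAngles, aatype: np.ndarray,
            use_symmetry: bool = True):
    """Mean absolute chi error in degrees, per chi index (NaN when empty)."""
    err, mask = chi_errors_deg(pred_chi, native_chi, aatype, use_symmetry)
    counts = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mae = np.where(counts > 0, err.sum(axis=0) / np.maximum(counts, 1), np.nan)
    return mae, counts


def per_residue_rmsd(pred: ProteinChain, native: ProteinChain,
                     use_symmetry: bool = True):
    """Side-chain heavy-atom RMSD after per-residue backbone superposition.

    For each residue the four backbone atoms (N, CA, C, O) of the prediction
    are superposed onto the native ones and the RMSD is computed over the
    side-chain heavy atoms including CB.  Residues without scoreable atoms
    in both structures (e.g. GLY) get NaN.  Returns (per-residue array,
    mean over scored residues).
    """
    if pred.sequence != native.sequence:
        raise ValueError("prediction and native sequences differ")
    L = len(pred)
    out = np.full(L, np.nan)
    for i in range(L):
        bb_ok = pred.atom_mask[i, :4].all() and native.atom_mask[i, :4].all()
        sc = pred.atom_mask[i, 4:] & native.atom_mask[i, 4:]
        if not bb_ok or not sc.any():
            continue
        transform = kabsch(pred.atom_coords[i, :4], native.atom_coords[i, :4])
        moved = transform.apply(pred.atom_coords[i])
        slots = np.nonzero(sc)[0] + 4
        res3 = R.ONE_TO_THREE[pred.sequence[i]]
        best = _rmsd_over(moved, native.atom_coords[i], slots)
        if use_symmetry and res3 in R.SYMMETRIC_SWAPS:
            relabeled = _apply_swaps(native.atom_coords[i], res3)
            best = min(best, _rmsd_over(moved, relabeled, slots))
        out[i] = best
    scored = ~np.isnan(out)
    mean = float(np.mean(out[scored])) if scored.any() else np.nan
    return out, mean


def _rmsd_over(a, b, slots):
    d = a[slots] - b[slots]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def _apply_swaps(coords, res3):
    out = coords.copy()
    names = R.ATOM14_NAMES[res3]
    for a, b in R.SYMMETRIC_SWAPS[res3]:
        ia, ib = names.index(a), names.index(b)
        out[[ia, ib]] = out[[ib, ia]]
    return out


def centrality(chain: ProteinChain) -> np.ndarray:
    """Per-residue label: 'core' (>= 20 neighbors), 'surface' (<= 15), 'neither'.

    Neighbors are other residues with CB-CB distance below 10 A (virtual CB
    for glycine); the residue itself is not counted.
    """
    cb = chain.cb_or_virtual()
    d = np.linalg.norm(cb[:, None] - cb[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    counts = (d < CENTRALITY_RADIUS).sum(axis=1)
    labels = np.full(len(chain), "neither", dtype=object)
    labels[counts >= CORE_MIN_NEIGHBORS] = "core"
    labels[counts <= SURFACE_MAX_NEIGHBORS] = "surface"
    return labels


def bfactor_chi_filter(chain: ProteinChain,
                       cutoff: float = BFACTOR_CUTOFF) -> np.ndarray:
    """(L, 4) mask keeping chi angles whose side-chain atoms all have B <= cutoff.

    A chi is discarded when any atom of its defining quadruple beyond the
    backbone (N, CA, C, O) has a B-factor above the cutoff.  Chains without
    B-factors pass unchanged (all zeros count as passing).
    """
    keep = R.CHI_MASK_BY_RESTYPE[chain.aatype].copy()
    quad = R.CHI_ATOM14_IDX[chain.aatype]  # (L, 4, 4)
    safe = np.where(quad < 0, 0, quad)
    b = chain.b_factors[np.arange(len(chain))[:, None, None], safe]
    sidechain_atom = safe >= 4  # slots beyond N/CA/C/O (CB onward)
    high = (b > cutoff) & sidechain_atom
    keep &= ~high.any(axis=2)
    return keep


def evaluate(pred: ProteinChain, native: ProteinChain,
             bfactor_cutoff: float = None,
             tol_deg: float = ROTAMER_TOLERANCE_DEG,
             use_symmetry: bool = True) -> dict:
    """Full metric report, overall and stratified by centrality and residue type."""
    from .structure import extract_chi

    pred_chi = extract_chi(pred)
    native_chi = extract_chi(native)
    if bfactor_cutoff is not None:
        bf = bfactor_chi_filter(native, bfactor_cutoff)
        native_chi = ChiAngles(native_chi.chi * bf, native_chi.chi_mask & bf)

    recovered, has_chi = rotamer_recovered(pred_chi, native_chi, pred.aatype,
                                           tol_deg, use_symmetry)
    mae, mae_counts = chi_mae(pred_chi, native_chi, pred.aatype, use_symmetry)
    rmsd_per_res, rmsd_mean = per_residue_rmsd(pred, native, use_symmetry)
    labels = centrality(native)

    def stratum(sel):
        n = int((sel & has_chi).sum())
        rr = float(recovered[sel & has_chi].mean() * 100) if n else np.nan
        scored = sel & ~np.isnan(rmsd_per_res)
        rmsd = float(rmsd_per_res[scored].mean()) if scored.any() else np.nan
        return {"n_residues": n, "rotamer_recovery_pct": rr, "rmsd": rmsd}

    report = {
        "overall": stratum(np.ones(len(pred), dtype=bool)),
        "chi_mae_deg": [float(m) if np.isfinite(m) else None for m in mae],
        "chi_counts": mae_counts.tolist(),
        "clashscore": clashscore(pred),
        "centrality": {name: stratum(labels == name)
                       for name in ("core", "surface", "neither")},
        "by_residue_type": {},
    }
    for aa in sorted(set(pred.sequence)):
        sel = np.array([c == aa for c in pred.sequence])
        if (sel & has_chi).any():
            report["by_residue_type"][R.ONE_TO_THREE[aa]] = stratum(sel)
    return report
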