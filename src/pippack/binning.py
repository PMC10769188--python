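"""Discretization of chi angles into angular bins with within-bin offsets.

The torsion domain [-pi, pi) is split into ``n_bins`` equal half-open bins
(72 bins of 5 degrees by default).  An angle is represented by its bin index
plus a signed fractional offset in [-1/2, 1/2) relative to the bin center,
in bin-width units, which makes bin+offset <-> angle an exact round trip.
"""

from __future__ import annotations

import numpy as np

from .geometry import wrap_angle

N_BINS = 72  # 5-degree bins over [-pi, pi)


def bin_width(n_bins: int = N_BINS) -> float:
    return 2.0 * np.pi / n_bins


def bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    w = bin_width(n_bins)
    return -np.pi + (np.arange(n_bins) + 0.5) * w


def discretize(chi, n_bins: int = N_BINS):
    """Angle -> (bin index, offset in bin widths within [-1/2, 1/2))."""
    chi = wrap_angle(chi)
    w = bin_width(n_bins)
    frac = (chi + np.pi) / w
    idx = np.clip(np.floor(frac).astype(np.int64), 0, n_bins - 1)
    offset = frac - idx - 0.5
    return idx, offset


def undiscretize(bin_idx, offset, n_bins: int = N_BINS):
    """(bin index, offset) -> angle in [-pi, pi); exact inverse of discretize."""
    w = bin_width(n_bins)
    return wrap_angle(-np.pi + (np.asarray(bin_idx) + 0.5 + np.asarray(offset)) * w)


def decode_mode_arrays(logits: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Angle of the distribution mode; ties go to the lowest bin index."""
    idx = np.argmax(logits, axis=-1)
    off = np.take_along_axis(offsets, idx[..., None], axis=-1)[..., 0]
    return undiscretize(idx, off, logits.shape[-1])
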