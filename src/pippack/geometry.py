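"""Rigid-body and internal-coordinate geometry.

Angles are radians on the half-open interval [-pi, pi) throughout the
package.  :func:`place_atom` is written against :mod:`pippack.ops`, so it is
differentiable when handed Tensors and plain NumPy otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ops as A


def wrap_angle(angle):
    """Wrap to [-pi, pi)."""
    return np.mod(np.asarray(angle) + np.pi, 2.0 * np.pi) - np.pi


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 (IUPAC convention), vectorized.

    Accepts arrays of shape (..., 3); returns angles in [-pi, pi).
    """
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return wrap_angle(np.arctan2(y, x))


def bond_angle(p0, p1, p2) -> np.ndarray:
    """Angle p0-p1-p2 in radians."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _normalize(v):
    return A.div(v, A.norm(v, axis=-1, keepdims=True))


def place_atom(a, b, c, bond: float, angle, torsion):
    """Place atom X from three parents by internal coordinates (NERF).

    X is bonded to ``a`` at distance ``bond``, with angle X-a-b equal to
    ``angle`` and dihedral X-a-b-c equal to ``torsion`` (radians).  ``angle``
    and ``torsion`` may be scalars or Tensors; parents are (...,3) points.
    """
    ba = A.sub(a, b)
    cb = A.sub(b, c)
    u1 = _normalize(ba)
    n = _normalize(A.cross(cb, ba))
    m = A.cross(n, u1)
    d1 = A.mul(A.cos(angle), -bond)
    d2 = A.mul(A.mul(A.sin(angle), A.cos(torsion)), bond)
    d3 = A.mul(A.mul(A.sin(angle), A.sin(torsion)), bond)
    disp = A.add(A.add(A.mul(u1, _reshape_last(d1)), A.mul(m, _reshape_last(d2))),
                 A.mul(n, _reshape_last(d3)))
    return A.add(a, disp)


def _reshape_last(x):
    """Append a trailing axis so scalars broadcast against (...,3) vectors."""
    if A.is_tensor(x):
        return A.reshape(x, tuple(np.shape(x.data)) + (1,)) if x.data.ndim else x
    arr = np.asarray(x, dtype=np.float64)
    return arr[..., None] if arr.ndim else arr


def ideal_cb(n, ca, c) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C coordinates.

    Uses the standard tetrahedral construction from the local backbone frame;
    also used as the virtual C-beta for glycine.
    """
    n, ca, c = (np.asarray(x) for x in (n, ca, c))
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


@dataclass
class RigidTransform:
    """Batch of rigid transforms x -> R @ x + t.

    rotation: (..., 3, 3) orthonormal with det +1; translation: (..., 3).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)

    @classmethod
    def identity(cls, shape=()) -> "RigidTransform":
        rot = np.broadcast_to(np.eye(3), tuple(shape) + (3, 3)).copy()
        return cls(rot, np.zeros(tuple(shape) + (3,)))

    def apply(self, points) -> np.ndarray:
        """Transform (...,3) points (row-vector convention)."""
        return np.squeeze(self.rotation @ np.asarray(points)[..., None], -1) \
            + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            np.squeeze(self.rotation @ other.translation[..., None], -1)
            + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_t = np.swapaxes(self.rotation, -1, -2)
        return RigidTransform(rot_t, -np.squeeze(rot_t @ self.translation[..., None], -1))

    def orthonormality_error(self) -> float:
        rtr = np.swapaxes(self.rotation, -1, -2) @ self.rotation
        return float(np.max(np.abs(rtr - np.eye(3))))

    def __getitem__(self, idx) -> "RigidTransform":
        return RigidTransform(self.rotation[idx], self.translation[idx])

    def __len__(self) -> int:
        return self.rotation.shape[0]


def frames_from_backbone(n, ca, c, tol: float = 1e-7) -> RigidTransform:
    """Backbone frame per residue by Gram-Schmidt.

    x-axis along C-CA, the N-CA direction fixes the xy-plane, z completes a
    right-handed system; the translation is the CA position.  Raises for
    (near-)collinear N, CA, C.
    """
    n, ca, c = (np.asarray(x, dtype=np.float64) for x in (n, ca, c))
    e1 = c - ca
    e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    u = n - ca
    e2 = u - np.sum(u * e1, axis=-1, keepdims=True) * e1
    norms = np.linalg.norm(e2, axis=-1, keepdims=True)
    if np.any(norms < tol):
        bad = np.nonzero(norms[..., 0] < tol)[0]
        raise ValueError(f"collinear N/CA/C backbone at residue index {bad[0]}")
    e2 = e2 / norms
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=-1)  # columns are the basis vectors
    return RigidTransform(rot, ca)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Both arrays are (n_points, 3); returns the transform minimizing the RMSD
    of the moved mobile points to the target (proper rotation only).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return RigidTransform(rot, mu_t - rot @ mu_m)


def random_rigid_transform(rng: np.random.Generator,
                           translation_scale: float = 10.0) -> RigidTransform:
    """Uniformly random rotation (QR of a Gaussian matrix) plus translation."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.standard_normal(3) * translation_scale
    return RigidTransform(q, t)
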