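"""Rigid-body superposition (Kabsch) and the transform algebra.

The Kabsch fit is the SVD form with the standard reflection correction, so
the returned rotation is always proper.  Degenerate (rank-deficient) point
sets produce a best-effort fit plus a warning rather than an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PairingError

__all__ = ["RigidTransform", "kabsch_fit", "apply_transform", "rmsd_nofit"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion r -> R r + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """self ∘ first: apply ``first``, then ``self``."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def as_row(self) -> np.ndarray:
        """Flattened 12-vector (9 rotation entries row-major + translation)."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_row(cls, row: np.ndarray) -> "RigidTransform":
        row = np.asarray(row, dtype=float)
        return cls(row[:9].reshape(3, 3), row[9:12])


def kabsch_fit(reference: np.ndarray, mobile: np.ndarray
               ) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid fit of ``mobile`` onto ``reference``.

    Returns the transform T minimizing RMSD(T(mobile), reference) over all
    rotations+translations, and that minimal RMSD.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PairingError(
            f"point sets must be equal (n,3) arrays, got {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise PairingError("need at least 3 point pairs")
    cr = ref.mean(axis=0)
    cm = mob.mean(axis=0)
    H = (mob - cm).T @ (ref - cr)
    U, S, Vt = np.linalg.svd(H)
    # planar sets (one vanishing singular value) are fine once properness is
    # enforced; only collinear sets leave the rotation under-determined
    if S[1] < 1e-10 * max(S[0], 1.0):
        warnings.warn("degenerate (near-collinear) point set; "
                      "superposition is not unique", stacklevel=2)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    tr = RigidTransform(R, t)
    rmsd = rmsd_nofit(ref, tr.apply(mob))
    return tr, rmsd


def apply_transform(structure, t: RigidTransform):
    """Return a copy of ``structure`` with every model's coordinates mapped
    through the rigid transform."""
    out = structure.copy()
    out.coords = structure.coords @ t.rotation.T + t.translation
    return out


def rmsd_nofit(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation without superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PairingError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
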