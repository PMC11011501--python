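"""Rigid-body superposition and RMSD primitives.

SVD-based Kabsch superposition with a reflection guard, fixed-frame RMSD
(no re-fitting), and minimum pairwise distances.  These are the geometric
building blocks for receptor-aligned ligand-pose clustering, binding-mode
distance tables, and ligand grafting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class RigidTransform:
    """A proper rigid motion x -> rotation @ x + translation (Angstrom)."""

    rotation: np.ndarray     # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray
               ) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimising the RMSD of the mobile
    points onto the reference, and the fitted RMSD in Angstrom.  Uniform
    weights; reflections are excluded by the determinant guard.  Requires
    at least 3 non-collinear point pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must be (N, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition needs at least 3 points")

    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    P = mobile - mob_c
    Q = reference - ref_c

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line undetermined
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    transform = RigidTransform(R, t)
    fitted = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return transform, rmsd


def rmsd_no_fit(A: np.ndarray, B: np.ndarray) -> float:
    """RMSD between two matched coordinate sets without re-fitting.

    Atom matching is by index order; callers present matched selections.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"coordinate sets differ in shape: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def min_heavy_distance(selA: np.ndarray, selB: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between two coordinate sets."""
    selA = np.atleast_2d(np.asarray(selA, dtype=float))
    selB = np.atleast_2d(np.asarray(selB, dtype=float))
    if selA.size == 0 or selB.size == 0:
        raise ValueError("distance between empty coordinate sets is undefined")
    return float(cdist(selA, selB).min())
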