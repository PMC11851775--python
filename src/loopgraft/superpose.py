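"""Rigid-body superposition and inter-chain CA distance matrices.

The pairing algorithm consumes a matrix of all pairwise CA-CA Euclidean
distances between two chains placed in a common frame.  That frame can
come from an external structure-alignment program (pass pre-superposed
coordinates and the identity transform) or from the least-squares
iterative superposition implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structures import ChainStructure


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, in Å."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-6):
            raise ValueError("rotation is not proper (det != +1)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def kabsch(points_a: np.ndarray, points_b: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``points_b`` onto ``points_a``.

    Proper rotation enforced (no reflection).  Requires >= 3
    non-collinear point pairs.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point lists must be matching (n, 3) arrays")
    if len(a) < 3:
        raise ValueError("at least 3 point pairs are required")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca_, b - cb_
    if np.linalg.matrix_rank(b0, tol=1e-9) < 2 or \
       np.linalg.matrix_rank(a0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(a0, b0)
    R = rot.as_matrix()
    return RigidTransform(R, ca_ - R @ cb_)


def rmsd(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Root-mean-square deviation between paired point sets, in Å."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("point lists must be non-empty and of equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superposed_rmsd(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (crystal-vs-model comparison)."""
    t = kabsch(points_a, points_b)
    return rmsd(points_a, t.apply(points_b))


def pairwise_ca_distances(a: ChainStructure, b: ChainStructure,
                          transform: RigidTransform | None = None) -> np.ndarray:
    """n_A x n_B matrix of |ca_a(i) - T(ca_b(j))| distances in Å."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both chains must be non-empty")
    if transform is None:
        transform = RigidTransform.identity()
    return cdist(a.coords, transform.apply(b.coords))


def iterative_superpose(a: ChainStructure, b: ChainStructure,
                        seed_pairs, params=None, max_iter: int = 20):
    """Alternate Kabsch fitting on the current pair set with greedy
    re-pairing until the pair set is stable (or ``max_iter``).

    ``seed_pairs`` is a Pairing (>= 3 pairs) from a user alignment or an
    SSE-anchored guess.  Returns ``(transform, pairing)``; on oscillation
    the best-RMSD iterate is returned with a warning.
    """
    from .pairing import PairingParams, pair_structures

    if params is None:
        params = PairingParams()
    pairs = list(seed_pairs.pairs)
    if len(pairs) < 3:
        raise ValueError("seed pairing must contain at least 3 pairs")
    coords_a, coords_b = a.coords, b.coords

    seen: list[frozenset] = []
    best = None  # (rmsd, transform, pairing)
    transform = None
    for _ in range(max_iter):
        ia = [p.i for p in pairs]
        jb = [p.j for p in pairs]
        transform = kabsch(coords_a[ia], coords_b[jb])
        pairing = pair_structures(a, b, transform, params)
        if len(pairing.pairs) >= 3:
            ia2 = [p.i for p in pairing.pairs]
            jb2 = [p.j for p in pairing.pairs]
            fit = rmsd(coords_a[ia2], transform.apply(coords_b[jb2]))
        else:
            fit = np.inf
        if best is None or fit < best[0]:
            best = (fit, transform, pairing)
        key = frozenset((p.i, p.j) for p in pairing.pairs)
        if key == frozenset((p.i, p.j) for p in pairs):
            return transform, pairing
        if key in seen:
            warnings.warn("iterative superposition oscillated; returning "
                          "best-RMSD iterate", stacklevel=2)
            return best[1], best[2]
        seen.append(key)
        if not pairing.pairs:
            warnings.warn("no residue pairs within threshold; chains share "
                          "no common geometry", stacklevel=2)
            return transform, pairing
        pairs = list(pairing.pairs)
    warnings.warn("iterative superposition did not converge in "
                  f"{max_iter} iterations; returning best-RMSD iterate",
                  stacklevel=2)
    return best[1], best[2]
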