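"""Optimal rigid-body superposition via the quaternion (Kearsley) method.

This is the primitive behind every alignment stage: given two point sets in
index correspondence, find the proper rotation and translation minimizing the
(optionally weighted) RMSD.  The minimal squared deviation is the smallest
eigenvalue of a symmetric 4x4 matrix built from coordinate sums; the matching
eigenvector is the rotation quaternion.  Improper rotations are never
returned — enantiomers are handled upstream by an explicit mirror branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SuperpositionResult",
    "geometric_center",
    "rmsd",
    "quaternion_superpose",
    "superpose_mirror_allowed",
]


def _as_points(coords) -> np.ndarray:
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    return pts


def _weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float).reshape(-1)
    if len(w) != n:
        raise ValueError("weights length mismatch")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w


def geometric_center(coords, weights=None) -> np.ndarray:
    """Weighted mean position; unit weights give the geometric center."""
    pts = _as_points(coords)
    w = _weights(len(pts), weights)
    return w @ pts / w.sum()


def rmsd(ref_coords, mov_coords, weights=None) -> float:
    """Plain weighted RMSD of two corresponding point sets — no fitting."""
    ref = _as_points(ref_coords)
    mov = _as_points(mov_coords)
    if ref.shape != mov.shape:
        raise ValueError(f"point count mismatch: {len(ref)} vs {len(mov)}")
    w = _weights(len(ref), weights)
    sq = np.einsum("ij,ij->i", ref - mov, ref - mov)
    return float(np.sqrt(w @ sq / w.sum()))


@dataclass
class SuperpositionResult:
    """Proper rotation + translations aligning ``mov`` onto ``ref``.

    The alignment maps a moving point x to
    ``rotation @ (x - translation_mov) + translation_ref`` where the two
    translations are the weighted centers of the input sets.
    """

    rotation: np.ndarray
    translation_ref: np.ndarray
    translation_mov: np.ndarray
    rmsd: float
    mirrored: bool = False

    def transform(self, coords) -> np.ndarray:
        """Apply the fitted rigid motion to arbitrary coordinates (..., 3)."""
        pts = np.asarray(coords, dtype=float)
        moved = pts - self.translation_mov
        if self.mirrored:
            moved = -moved
        return moved @ self.rotation.T + self.translation_ref


def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    q0, q1, q2, q3 = q
    return np.array(
        [
            [q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3, 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3, 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3],
        ]
    )


def _kearsley_matrix(ref: np.ndarray, mov: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Difference/sum coordinates of the centered sets, weighted by sqrt(w)
    # through the quadratic forms below.
    m = mov - ref
    p = mov + ref
    xm, ym, zm = m[:, 0], m[:, 1], m[:, 2]
    xp, yp, zp = p[:, 0], p[:, 1], p[:, 2]

    def s(u, v):
        return float(np.sum(w * u * v))

    K = np.empty((4, 4))
    K[0, 0] = s(xm, xm) + s(ym, ym) + s(zm, zm)
    K[0, 1] = K[1, 0] = s(yp, zm) - s(ym, zp)
    K[0, 2] = K[2, 0] = s(xm, zp) - s(xp, zm)
    K[0, 3] = K[3, 0] = s(xp, ym) - s(xm, yp)
    K[1, 1] = s(yp, yp) + s(zp, zp) + s(xm, xm)
    K[1, 2] = K[2, 1] = s(xm, ym) - s(xp, yp)
    K[1, 3] = K[3, 1] = s(xm, zm) - s(xp, zp)
    K[2, 2] = s(xp, xp) + s(zp, zp) + s(ym, ym)
    K[2, 3] = K[3, 2] = s(ym, zm) - s(yp, zp)
    K[3, 3] = s(xp, xp) + s(yp, yp) + s(zm, zm)
    return K


def quaternion_superpose(ref_coords, mov_coords, weights=None) -> SuperpositionResult:
    """Optimal proper-rotation superposition of ``mov`` onto ``ref``.

    Both sets are centered on their weighted means; the smallest eigenvalue of
    the Kearsley 4x4 matrix gives the minimal weighted squared deviation and
    its eigenvector the rotation quaternion.  With degenerate eigenvalues
    (symmetric point sets) the RMSD is still unique; the eigenvector returned
    by the symmetric eigensolver fixes the rotation deterministically.
    """
    ref = _as_points(ref_coords)
    mov = _as_points(mov_coords)
    if ref.shape != mov.shape:
        raise ValueError(f"point count mismatch: {len(ref)} vs {len(mov)}")
    w = _weights(len(ref), weights)

    c_ref = geometric_center(ref, w)
    c_mov = geometric_center(mov, w)
    ref0 = ref - c_ref
    mov0 = mov - c_mov

    K = _kearsley_matrix(ref0, mov0, w)
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, 0]  # eigenvector of the smallest eigenvalue
    rot = _quaternion_to_matrix(q)
    # Recompute the RMSD from the rotated coordinates: sqrt(lambda_min) loses
    # half the significant digits when the fit is nearly exact.
    moved = mov0 @ rot.T
    sq = np.einsum("ij,ij->i", moved - ref0, moved - ref0)
    return SuperpositionResult(
        rotation=rot,
        translation_ref=c_ref,
        translation_mov=c_mov,
        rmsd=float(np.sqrt(w @ sq / w.sum())),
    )


def superpose_mirror_allowed(ref_coords, mov_coords, weights=None) -> SuperpositionResult:
    """Best of the proper superposition and the mirror-image superposition.

    The mover is inverted through its weighted center for the mirror branch
    (point inversion differs from any mirror plane only by a proper rotation,
    which the fit absorbs).  ``mirrored`` flags which branch won; ties go to
    the proper branch.
    """
    proper = quaternion_superpose(ref_coords, mov_coords, weights)
    mov = _as_points(mov_coords)
    w = _weights(len(mov), weights)
    c_mov = geometric_center(mov, w)
    inverted = 2 * c_mov - mov
    mirrored = quaternion_superpose(ref_coords, inverted, weights)
    if mirrored.rmsd < proper.rmsd:
        return SuperpositionResult(
            rotation=mirrored.rotation,
            translation_ref=mirrored.translation_ref,
            translation_mov=c_mov,
            rmsd=mirrored.rmsd,
            mirrored=True,
        )
    return proper
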