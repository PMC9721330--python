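"""Cluster shape descriptors: gyration tensor, R_g, asphericity, anisotropy.

RMSD_N alone does not say whether the superimposed clusters were compact or
elongated, so each compared cluster is summarized by the gyration tensor

    S_ij = (1/N) sum_k (r_k - GC)_i (r_k - GC)_j

over its N selected atoms, where GC is the unweighted geometric center.  The
tensor is normalized by N so that the trace identity rg^2 = lambda_min +
lambda_med + lambda_max yields the conventional radius of gyration; an
unnormalized tensor is available via ``normalize=False``.

The auxiliary descriptors follow the standard polymer-physics definitions:
asphericity b = lambda_max - (lambda_med + lambda_min)/2, acylindricity
c = lambda_med - lambda_min, and relative shape anisotropy
kappa^2 = (b^2 + 3/4 c^2) / (sum lambda)^2, which is 0 for a sphere, 1 for a
rod and 1/4 for a flat disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GyrationMetrics",
    "gyration_tensor",
    "principal_moments",
    "radius_of_gyration",
    "shape_descriptors",
    "inertia_moments",
    "gyration_metrics",
]


def gyration_tensor(coords, normalize: bool = True) -> np.ndarray:
    """Symmetric 3x3 gyration tensor (Å²) about the geometric center."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    d = pts - pts.mean(axis=0)
    S = d.T @ d
    if normalize:
        S /= len(pts)
    return S


def principal_moments(tensor) -> tuple[float, float, float]:
    """Eigenvalues of a symmetric tensor, ascending (λ_min, λ_med, λ_max)."""
    S = np.asarray(tensor, dtype=float)
    if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("tensor must be symmetric 3x3")
    lam = np.linalg.eigvalsh(S)
    return (float(lam[0]), float(lam[1]), float(lam[2]))


def radius_of_gyration(moments) -> float:
    """R_g (Å): square root of the summed principal moments."""
    lam = np.asarray(moments, dtype=float)
    if np.any(lam < -1e-12):
        raise ValueError("principal moments must be non-negative")
    return float(np.sqrt(np.clip(lam, 0.0, None).sum()))


def shape_descriptors(moments) -> tuple[float, float, float]:
    """(asphericity b, acylindricity c, relative shape anisotropy κ²).

    For a degenerate cluster with zero total moment all three are defined
    as 0.
    """
    lmin, lmed, lmax = (float(x) for x in moments)
    if not lmin <= lmed <= lmax:
        raise ValueError("moments must be sorted ascending")
    total = lmin + lmed + lmax
    if total <= 0:
        return (0.0, 0.0, 0.0)
    b = lmax - 0.5 * (lmed + lmin)
    c = lmed - lmin
    kappa2 = (b * b + 0.75 * c * c) / (total * total)
    return (b, c, float(kappa2))


def inertia_moments(coords, masses) -> tuple[float, float, float]:
    """Principal moments of inertia (Da·Å²) about the center of mass, ascending."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float).reshape(-1)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if len(m) != len(pts) or np.any(m <= 0):
        raise ValueError("masses must be positive and match the point count")
    com = m @ pts / m.sum()
    d = pts - com
    r2 = np.einsum("ij,ij->i", d, d)
    I = np.diag([float(np.sum(m * r2))] * 3) - np.einsum("i,ij,ik->jk", m, d, d)
    lam = np.linalg.eigvalsh(I)
    return (float(lam[0]), float(lam[1]), float(lam[2]))


@dataclass
class GyrationMetrics:
    """Shape summary of one cluster of atoms."""

    tensor: np.ndarray
    moments: tuple[float, float, float]
    rg: float
    asphericity: float
    acylindricity: float
    anisotropy: float
    inertia: tuple[float, float, float] | None = None


def gyration_metrics(coords, masses=None) -> GyrationMetrics:
    """All shape descriptors for one cluster; inertia only if masses given."""
    S = gyration_tensor(coords)
    lam = principal_moments(S)
    b, c, kappa2 = shape_descriptors(lam)
    inertia = inertia_moments(coords, masses) if masses is not None else None
    return GyrationMetrics(
        tensor=S,
        moments=lam,
        rg=radius_of_gyration(lam),
        asphericity=b,
        acylindricity=c,
        anisotropy=kappa2,
        inertia=inertia,
    )
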