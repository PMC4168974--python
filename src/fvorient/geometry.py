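"""Rigid-body mathematics: least-squares superposition, principal axes, angles.

Everything downstream (orientation measures, docking angles, grafting) is
built from three primitives: the Kabsch least-squares superposition of
corresponding point sets, principal axes of a coordinate cloud, and the
torsion angle of four points.  All angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "superpose",
    "principal_axes",
    "vector_angle",
    "torsion_angle",
    "GeometryError",
]


class GeometryError(ValueError):
    """Degenerate geometry (too few points, collinear targets, zero vectors)."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t``.

    Attributes
    ----------
    rotation : (3, 3) ndarray
        Orthonormal rotation matrix with determinant +1 (reflections are
        never produced by :func:`superpose`).
    translation : (3,) ndarray
        Translation in Angstroms, applied after the rotation.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        """Rotate a direction vector (no translation)."""
        return np.asarray(vec, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    Point correspondence is given by row order.  The returned transform
    minimises the root-mean-square deviation; reflections are excluded by
    forcing the rotation determinant to +1.

    Parameters
    ----------
    mobile, target : (N, 3) arrays with N >= 3.

    Returns
    -------
    (RigidTransform, float)
        The optimal transform and the RMSD (Angstrom) it achieves.

    Raises
    ------
    GeometryError
        If fewer than 3 points are given, shapes disagree, or the target
        points are (near-)collinear so the rotation is under-determined.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(target, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError(f"point sets must both be (N, 3); got {X.shape} vs {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points to superpose, got {n}")

    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    X0 = X - xc
    Y0 = Y - yc

    # Collinear (rank < 2) targets leave a free rotation about the line.
    s_target = np.linalg.svd(Y0, compute_uv=False)
    if s_target[1] < 1e-8 * max(1.0, s_target[0]):
        raise GeometryError("target points are collinear; rotation under-determined")

    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    diff = transform.apply(X) - Y
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return transform, rmsd


def principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of a coordinate cloud, ordered by decreasing variance.

    The axes are unit eigenvectors of the coordinate covariance matrix.  Sign
    convention: the first axis is oriented to have positive projection onto
    the vector from the first to the last input point (for a peptide ordered
    N to C this orients the major axis N->C); the second axis follows the
    same rule where that projection is non-zero, and the third completes a
    right-handed set.

    Returns
    -------
    (axes, centroid)
        ``axes`` is a (3, 3) array whose *rows* are the axes; ``centroid``
        the (3,) mean coordinate.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 2:
        raise GeometryError("principal_axes needs an (N, 3) array with N >= 2")
    centroid = P.mean(axis=0)
    C = np.cov((P - centroid).T, bias=True) if P.shape[0] > 1 else np.zeros((3, 3))
    if np.allclose(P, P[0], atol=1e-12):
        raise GeometryError("all points identical; axes undefined")
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T
    head_to_tail = P[-1] - P[0]
    for i in range(2):
        proj = axes[i] @ head_to_tail
        if abs(proj) > 1e-12 and proj < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes, centroid


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("zero-length vector in angle computation")
    c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def torsion_angle(p1, p2, p3, p4) -> float:
    """Torsion (dihedral) angle of four points, degrees in (-180, 180].

    IUPAC sign convention: viewed along the p2->p3 axis, a clockwise rotation
    from the p1 projection to the p4 projection is positive — equivalently,
    right-handed about the p2->p3 direction.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.linalg.norm(b1)
    if min(np.linalg.norm(b0), n1, np.linalg.norm(b2)) < 1e-9:
        raise GeometryError("coincident consecutive points in torsion")
    b1 = b1 / n1
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    if min(np.linalg.norm(v), np.linalg.norm(w)) < 1e-9:
        raise GeometryError("collinear points in torsion; angle undefined")
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
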