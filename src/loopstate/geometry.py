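"""Rigid-body superposition, helix axes, rotations and projections.

This is the geometric kernel every conformational metric builds on:

* :func:`superpose` -- closed-form least-squares rigid superposition
  (Kabsch, via SVD with determinant correction for reflections);
* :func:`fit_helix_axis` -- helix axis as the principal direction of the
  running centers of four consecutive CA atoms, which is stable even for
  short loops like the nine-residue ICL2;
* :func:`rotate_about_axis` -- right-handed rotation about an axis line;
* :func:`axial_position` -- signed, unclamped projection of a point onto
  a line segment direction (used for the TM5 vertical-shift metric).

Distances are Angstrom, angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ParameterError


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation."""

    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ParameterError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise ParameterError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def apply_transform(t: RigidTransform, positions: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t to one position or an (n, 3) array of positions."""
    pos = np.asarray(positions, dtype=float)
    return pos @ t.rotation.T + t.translation


@dataclass(frozen=True)
class HelixAxis:
    """A helix axis line: a point on the axis and a unit direction.

    The direction points from lower to higher residue numbers.
    """

    point: np.ndarray
    direction: np.ndarray
    residue_range: tuple[int, int] | None = None

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ParameterError(f"direction must be unit length, |d| = {norm}")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / norm)


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform minimizing the RMSD of the transformed mobile
    points to the reference points, and that minimum RMSD.  Requires at
    least three non-collinear points in each set.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ParameterError("mobile and reference must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points to superpose, got {n}")
    cm, cr = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cm, Q - cr
    for label, X in (("mobile", Pc), ("reference", Qc)):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] < 1e-8 * max(1.0, s[0]):
            raise DegenerateGeometryError(f"{label} points are (nearly) collinear")
    C = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((apply_transform(transform, P) - Q) ** 2, axis=1))))
    return transform, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("rmsd: shapes must match")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fit_helix_axis(
    ca_positions: np.ndarray, residue_range: tuple[int, int] | None = None
) -> HelixAxis:
    """Fit a helix axis to CA positions ordered by residue number.

    Local helix centers ``c_i = mean(CA_i .. CA_{i+3})`` cancel most of the
    helical wobble; the axis is the principal direction of those centers,
    oriented from lower to higher residue numbers.  Needs at least five
    consecutive residues.
    """
    ca = np.asarray(ca_positions, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ParameterError("ca_positions must be (n, 3)")
    if ca.shape[0] < 5:
        raise DegenerateGeometryError(
            f"helix axis needs >= 5 residues, got {ca.shape[0]}"
        )
    centers = np.stack([ca[i : i + 4].mean(axis=0) for i in range(ca.shape[0] - 3)])
    mean = centers.mean(axis=0)
    _, _, Vt = np.linalg.svd(centers - mean)
    direction = Vt[0]
    span = centers[-1] - centers[0]
    if np.linalg.norm(span) < 1e-10:
        raise DegenerateGeometryError("helix centers are coincident")
    if direction @ span < 0:
        direction = -direction
    return HelixAxis(mean, direction / np.linalg.norm(direction), residue_range)


def rotate_about_axis(
    positions: np.ndarray, axis: HelixAxis, angle_deg: float
) -> np.ndarray:
    """Right-handed rotation of positions by ``angle_deg`` about the axis line.

    Points on the axis are fixed.
    """
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis.direction)
    pos = np.asarray(positions, dtype=float)
    return rot.apply(pos - axis.point) + axis.point


def axial_position(
    point: np.ndarray, seg_start: np.ndarray, seg_end: np.ndarray
) -> float:
    """Signed, unclamped projection of ``point`` onto the seg_start->seg_end line.

    Returns ``(point - seg_start) . u`` with ``u`` the unit segment direction;
    zero at ``seg_start``, the segment length at ``seg_end``, negative behind
    the start.
    """
    a = np.asarray(seg_start, dtype=float)
    b = np.asarray(seg_end, dtype=float)
    p = np.asarray(point, dtype=float)
    seg = b - a
    norm = np.linalg.norm(seg)
    if norm < 1e-10:
        raise DegenerateGeometryError("zero-length segment")
    return float((p - a) @ (seg / norm))


def wrap_angle(angle_deg):
    """Wrap angle(s) in degrees into the interval (-180, 180]."""
    a = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    if a.ndim == 0:
        return float(a)
    return a
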