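"""Rigid transforms, lines, planes and Euler-angle helpers.

All coordinates are in millimetres. Rotations are 3x3 orthonormal matrices
with determinant +1 acting on column vectors (``p' = R @ p + t``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FemaxesError

_UNIT_TOL = 1e-9


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


def unit(v) -> np.ndarray:
    """Return ``v`` normalized to unit length."""
    v = _as_vec3(v)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise FemaxesError("cannot normalize zero vector")
    return v / n


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R @ p + t``.

    Invariants: ``R.T @ R = I`` and ``det(R) = +1`` within 1e-9.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(self.translation)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise FemaxesError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise FemaxesError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Transform one point or an (N,3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_direction(self, d) -> np.ndarray:
        return np.asarray(d, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def __matmul__(self, other):
        if isinstance(other, RigidTransform):
            return self.compose(other)
        return NotImplemented


@dataclass(frozen=True)
class Line3:
    """Infinite oriented line given by a point and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = _as_vec3(self.point)
        d = _as_vec3(self.direction)
        if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
            raise FemaxesError("line direction must be unit length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)

    @staticmethod
    def through(a, b) -> "Line3":
        a = _as_vec3(a)
        return Line3(a, unit(_as_vec3(b) - a))

    def distance_to_point(self, q) -> float:
        q = np.asarray(q, dtype=float)
        w = q - self.point
        return float(np.linalg.norm(np.cross(w, self.direction), axis=-1))

    def project_param(self, q):
        """Signed parameter(s) of the orthogonal projection of ``q`` onto the line."""
        q = np.asarray(q, dtype=float)
        return (q - self.point) @ self.direction

    def at(self, t):
        return self.point + np.multiply.outer(np.asarray(t, dtype=float), self.direction)

    def transformed(self, T: RigidTransform) -> "Line3":
        return Line3(T.apply(self.point), T.apply_direction(self.direction))


@dataclass(frozen=True)
class Plane3:
    """Plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = _as_vec3(self.point)
        n = _as_vec3(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
            raise FemaxesError("plane normal must be unit length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, q):
        q = np.asarray(q, dtype=float)
        return (q - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two orthonormal in-plane directions (deterministic)."""
        n = self.normal
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = unit(np.cross(n, a))
        v = np.cross(n, u)
        return u, v

    def transformed(self, T: RigidTransform) -> "Plane3":
        return Plane3(T.apply(self.point), T.apply_direction(self.normal))


def closest_point_between_lines(a: Line3, b: Line3) -> tuple[np.ndarray, np.ndarray]:
    """Feet of the mutual perpendicular: (point on ``a``, point on ``b``).

    Raises for parallel lines.
    """
    d1, d2 = a.direction, b.direction
    c = np.cross(d1, d2)
    denom = np.dot(c, c)
    if denom < 1e-18:
        raise FemaxesError("lines are parallel")
    w = b.point - a.point
    t1 = np.dot(np.cross(w, d2), c) / denom
    t2 = np.dot(np.cross(w, d1), c) / denom
    return a.point + t1 * d1, b.point + t2 * d2


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (unit) axis by an angle in degrees (Rodrigues)."""
    k = unit(axis)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def rotation_x(angle_deg: float) -> np.ndarray:
    return rotation_about_axis([1, 0, 0], angle_deg)


def rotation_y(angle_deg: float) -> np.ndarray:
    return rotation_about_axis([0, 1, 0], angle_deg)


def rotation_z(angle_deg: float) -> np.ndarray:
    return rotation_about_axis([0, 0, 1], angle_deg)


def rotation_angle_rad(R) -> float:
    """Rotation angle of a proper rotation matrix, in radians."""
    R = np.asarray(R, dtype=float)
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def euler_xyz_intrinsic_deg(R) -> tuple[float, float, float]:
    """Decompose ``R = Rx(a) @ Ry(b) @ Rz(c)`` (intrinsic x-y-z); degrees."""
    R = np.asarray(R, dtype=float)
    b = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
    if abs(np.cos(b)) < 1e-9:
        # gimbal proximity: a and c are coupled; report a = 0
        a = 0.0
        c = np.arctan2(R[1, 0], R[1, 1])
    else:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
    return float(np.rad2deg(a)), float(np.rad2deg(b)), float(np.rad2deg(c))


def euler_xyz_to_matrix(a_deg: float, b_deg: float, c_deg: float) -> np.ndarray:
    return rotation_x(a_deg) @ rotation_y(b_deg) @ rotation_z(c_deg)


def random_rigid_transform(rng: np.random.Generator,
                           max_angle_deg: float = 360.0,
                           max_translation: float = 1000.0) -> RigidTransform:
    """Random rigid motion with per-axis Euler angles in [-max_angle, max_angle]
    degrees and per-axis translation in [-max_translation, max_translation] mm.
    """
    angles = rng.uniform(-max_angle_deg, max_angle_deg, size=3)
    t = rng.uniform(-max_translation, max_translation, size=3)
    R = rotation_x(angles[0]) @ rotation_y(angles[1]) @ rotation_z(angles[2])
    return RigidTransform(R, t)
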