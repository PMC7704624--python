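"""Least-squares geometric primitives: sphere, planar ellipse, ellipsoid.

These are the building blocks of the landmark refinement stages. All fits are
plain least squares (no robustification) and are equivariant under rigid
transforms of the input points.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError
from .transforms import unit

__all__ = ["SphereFit", "EllipseFit3D", "EllipsoidFit",
           "fit_sphere", "fit_ellipse_3d", "fit_ellipsoid", "fit_plane_tls",
           "fit_line_3d"]


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float
    algebraic_rms: float  # residual of the initial algebraic solve


@dataclass(frozen=True)
class EllipseFit3D:
    center: np.ndarray
    normal: np.ndarray
    major_axis_dir: np.ndarray
    semi_major: float
    semi_minor: float

    @property
    def foci(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.sqrt(max(self.semi_major ** 2 - self.semi_minor ** 2, 0.0))
        off = c * self.major_axis_dir
        return self.center + off, self.center - off


@dataclass(frozen=True)
class EllipsoidFit:
    center: np.ndarray
    axes: np.ndarray   # (3, 3) rows, right-handed orthonormal
    radii: np.ndarray  # sorted descending

    @property
    def major_axis(self) -> np.ndarray:
        return self.axes[0]


def _check_points(points, min_n: int, name: str) -> np.ndarray:
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(p) < min_n:
        raise DegenerateFitError(f"{name} needs at least {min_n} points, got {len(p)}")
    return p


def _span_singular_values(p: np.ndarray) -> np.ndarray:
    c = p - p.mean(axis=0)
    return np.linalg.svd(c, compute_uv=False)


def fit_sphere(points) -> SphereFit:
    """Algebraic least-squares sphere, refined by Gauss-Newton on the
    geometric residual ``|p - c| - r``. Exact on noiseless sphere samples.
    """
    p = _check_points(points, 4, "sphere fit")
    sv = _span_singular_values(p)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError("sphere fit: points are coplanar or collinear")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("sphere fit: non-positive squared radius")
    radius = float(np.sqrt(r2))
    algebraic_rms = float(np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - radius) ** 2)))

    # geometric refinement
    c, r = center.copy(), radius
    for _ in range(20):
        d = p - c
        dist = np.linalg.norm(d, axis=1)
        res = dist - r
        J = np.column_stack([-d / np.maximum(dist, 1e-300)[:, None], -np.ones(len(p))])
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        c = c + step[:3]
        r = r + step[3]
        if np.linalg.norm(step) < 1e-12 * max(1.0, r):
            break
    if r <= 0:
        raise DegenerateFitError("sphere fit: refinement collapsed")
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - c, axis=1) - r) ** 2)))
    return SphereFit(center=c, radius=float(r), rms_residual=rms, algebraic_rms=algebraic_rms)


def fit_plane_tls(points) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane: returns (centroid, unit normal)."""
    p = _check_points(points, 3, "plane fit")
    c = p.mean(axis=0)
    _, s, vt = np.linalg.svd(p - c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateFitError("plane fit: points are collinear")
    return c, vt[2]


def fit_line_3d(points) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line: returns (centroid, unit direction)."""
    p = _check_points(points, 2, "line fit")
    c = p.mean(axis=0)
    _, _, vt = np.linalg.svd(p - c, full_matrices=False)
    return c, vt[0]


def fit_ellipse_3d(points) -> EllipseFit3D:
    """Planar ellipse fit: TLS plane projection followed by a direct
    ellipse-specific conic fit (Halir & Flusser) in the plane.
    """
    p = _check_points(points, 6, "ellipse fit")
    centroid, normal = fit_plane_tls(p)
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(normal, a))
    v = np.cross(normal, u)
    q = p - centroid
    xy = np.column_stack([q @ u, q @ v])
    cx, cy, aa, bb, theta = _fit_ellipse_2d(xy)
    center = centroid + cx * u + cy * v
    major = np.cos(theta) * u + np.sin(theta) * v
    return EllipseFit3D(center=center, normal=normal, major_axis_dir=unit(major),
                        semi_major=float(aa), semi_minor=float(bb))


def _fit_ellipse_2d(xy: np.ndarray) -> tuple[float, float, float, float, float]:
    """Direct ellipse fit (Halir-Flusser variant of Fitzgibbon).

    Returns center (cx, cy), semi axes (a >= b) and major-axis angle.
    """
    x, y = xy[:, 0], xy[:, 1]
    # scale for conditioning
    scale = max(np.abs(xy).max(), 1e-12)
    xs, ys = x / scale, y / scale
    D1 = np.column_stack([xs ** 2, xs * ys, ys ** 2])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("ellipse fit: degenerate point configuration") from exc
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    try:
        eigval, eigvec = np.linalg.eig(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateFitError("ellipse fit failed") from exc
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.real(cond) > 0)[0]
    if len(ok) == 0:
        raise DegenerateFitError("ellipse fit: best conic is not an ellipse")
    a1 = np.real(eigvec[:, ok[0]])
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F on scaled coords
    A, B, C, D, E, F = coeffs
    # unscale: x = xs*scale
    A, B, C = A / scale ** 2, B / scale ** 2, C / scale ** 2
    D, E = D / scale, E / scale
    den = B ** 2 - 4 * A * C
    if den >= 0:
        raise DegenerateFitError("ellipse fit: conic is not an ellipse")
    cx = (2 * C * D - B * E) / den
    cy = (2 * A * E - B * D) / den
    # conic translated to its center: lam1*x'^2 + lam2*y'^2 + F0 = 0
    F0 = F + 0.5 * (D * cx + E * cy)
    Q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(Q)
    with np.errstate(invalid="raise", divide="raise"):
        try:
            r = np.sqrt(-F0 / lam)
        except FloatingPointError as exc:
            raise DegenerateFitError("ellipse fit: invalid axis lengths") from exc
    if r[0] >= r[1]:
        aa, bb, axis = r[0], r[1], vec[:, 0]
    else:
        aa, bb, axis = r[1], r[0], vec[:, 1]
    ang = np.arctan2(axis[1], axis[0])
    return float(cx), float(cy), float(aa), float(bb), float(ang)


def fit_ellipsoid(points) -> EllipsoidFit:
    """Algebraic least-squares quadric constrained to an ellipsoid.

    The 9-parameter quadric is solved linearly; if its signature is not an
    ellipsoid (common for near-cylindrical data, where the quadric is
    unbounded along the tube axis), the system is re-solved with a small
    ridge toward the isotropic quadric, which deterministically yields a
    valid ellipsoid with a very large major radius along the tube.
    """
    p = _check_points(points, 9, "ellipsoid fit")
    sv = _span_singular_values(p)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError("ellipsoid fit: points do not span 3D")
    mean = p.mean(axis=0)
    scale = sv[0] / np.sqrt(len(p)) or 1.0
    q = (p - mean) / scale
    x, y, z = q[:, 0], q[:, 1], q[:, 2]
    Dm = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z,
                          2 * x, 2 * y, 2 * z])
    sol, *_ = np.linalg.lstsq(Dm, np.ones(len(q)), rcond=None)
    A3 = np.array([[sol[0], sol[3], sol[4]],
                   [sol[3], sol[1], sol[5]],
                   [sol[4], sol[5], sol[2]]])
    g = sol[6:9]
    evals = np.linalg.eigvalsh(A3)
    if np.all(evals > 0):
        center_q = -np.linalg.solve(A3, g)
        rhs = 1.0 + center_q @ A3 @ center_q  # == 1 - g @ center_q
        w, V = np.linalg.eigh(A3)
        radii_sq = rhs / w
        if np.all(radii_sq > 0):
            radii = np.sqrt(radii_sq)
            return _finalize_ellipsoid(mean + center_q * scale, V.T, radii * scale)
    # ridge fallback: near-cylindrical or prism-like data leaves the quadric
    # (nearly) underdetermined; a small ridge toward the isotropic quadric
    # selects a valid ellipsoid deterministically, with a huge major radius
    # along the degenerate (tube) direction
    return _fit_ellipsoid_ridge(q, Dm, mean, scale)


def _fit_ellipsoid_ridge(q: np.ndarray, Dm: np.ndarray, mean: np.ndarray,
                         scale: float, mu: float = 1e-6) -> EllipsoidFit:
    n = len(q)
    s0 = np.zeros(9)
    s0[:3] = 1.0 / max(np.mean(np.einsum("ij,ij->i", q, q)), 1e-12)
    lhs = Dm.T @ Dm + mu * n * np.eye(9)
    rhs = Dm.T @ np.ones(n) + mu * n * s0
    sol = np.linalg.solve(lhs, rhs)
    A3 = np.array([[sol[0], sol[3], sol[4]],
                   [sol[3], sol[1], sol[5]],
                   [sol[4], sol[5], sol[2]]])
    g = sol[6:9]
    evals = np.linalg.eigvalsh(A3)
    if np.any(evals <= 0):
        raise DegenerateFitError("ellipsoid fit: quadric is not an ellipsoid")
    center_q = -np.linalg.solve(A3, g)
    rhs_c = 1.0 + center_q @ A3 @ center_q
    w, V = np.linalg.eigh(A3)
    radii_sq = rhs_c / w
    if np.any(radii_sq <= 0):
        raise DegenerateFitError("ellipsoid fit: invalid radii")
    return _finalize_ellipsoid(mean + center_q * scale, V.T,
                               np.sqrt(radii_sq) * scale)


def _skew(w):
    return np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])


def _finalize_ellipsoid(center, axes_rows, radii) -> EllipsoidFit:
    radii = np.asarray(radii, dtype=float)
    axes = np.asarray(axes_rows, dtype=float)
    order = np.argsort(radii)[::-1]
    # near-isotropic tie break: lexicographically largest direction first
    if radii[order[0]] - radii[order[1]] < 1e-6 * radii[order[0]]:
        cand = [order[0], order[1]]
        keys = [tuple(np.round(axes[i] * np.sign(axes[i][np.argmax(np.abs(axes[i]))]), 9))
                for i in cand]
        if keys[1] > keys[0]:
            order[[0, 1]] = order[[1, 0]]
    radii = radii[order]
    axes = axes[order]
    # canonical signs + right-handedness
    for i in range(3):
        j = np.argmax(np.abs(axes[i]))
        if axes[i][j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    if np.any(radii <= 0):
        raise DegenerateFitError("ellipsoid fit: non-positive radius")
    return EllipsoidFit(center=np.asarray(center, dtype=float), axes=axes, radii=radii)
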