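"""Parametric femur-like surface generator with analytic ground truth.

The generator assembles a femur from smoothly blended implicit primitives
(head sphere, neck capsule, bowed shaft capsule, trochanteric bumps, two
posterior condyle spheres, an anterior trochlear bridge and a carved
intercondylar groove) and extracts the surface with marching cubes. Ground
truth landmarks, axes and planes come from the construction itself, not from
the mesh, so they are exact up to floating point.

Canonical construction frame (right femur): x distal(-)/proximal(+),
y medial(-)/lateral(+), z posterior(-)/anterior(+). A left femur is the
mirror image across the x-z plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import marching_cubes

from .errors import GenerationError
from .mesh import SurfaceMesh, signed_volume
from .transforms import Line3, Plane3, RigidTransform, unit

__all__ = ["FemurSpec", "GroundTruth", "generate_femur", "default_spec"]

_BLEND = 2.0  # mm smooth-union band; primitives further apart stay exact


@dataclass(frozen=True)
class FemurSpec:
    """Generative parameters of a synthetic femur (all lengths in mm)."""

    side: str = "right"
    total_length: float = 450.0
    head_radius: float = 24.0
    neck_length: float = 55.0
    ccd_angle: float = 125.0      # neck-shaft angle, degrees
    version_angle: float = 15.0   # anteversion, degrees
    shaft_radius: float = 14.0
    shaft_bow: float = 5.0        # anterior sagittal offset at mid-shaft
    condyle_radius_medial: float = 22.0
    condyle_radius_lateral: float = 22.0
    condyle_elongation: float = 5.0    # extra posterior-distal semi-axis length
    condyle_separation: float = 50.0   # center-to-center, mediolateral
    epicondyle_offset: float = 4.0     # epicondylar protrusion beyond condyle
    trochanter_height_greater: float = 25.0  # SGT above neck base
    trochanter_height_lesser: float = 45.0   # LT below neck base
    groove_depth: float = 3.0     # intercondylar groove carve depth control
    voxel_pitch: float = 3.0      # marching-cubes grid pitch
    subdivisions: int = 1         # post-extraction subdivision + reprojection
    rng_seed: int = 0             # reserved; the construction is deterministic

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise GenerationError(f"side must be left|right, got {self.side!r}")
        for name in ("total_length", "head_radius", "neck_length", "shaft_radius",
                     "condyle_radius_medial", "condyle_radius_lateral",
                     "condyle_separation", "voxel_pitch"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if not 90.0 < self.ccd_angle < 180.0:
            raise GenerationError("ccd_angle must be in (90, 180) degrees")
        if not -45.0 < self.version_angle < 60.0:
            raise GenerationError("version_angle must be in (-45, 60) degrees")
        if self.shaft_bow < 0 or self.groove_depth < 0:
            raise GenerationError("shaft_bow and groove_depth must be >= 0")
        if self.total_length < 6 * self.head_radius:
            raise GenerationError("total_length too small for the head radius")

    def mirrored(self) -> "FemurSpec":
        return replace(self, side="left" if self.side == "right" else "right")


def default_spec(**overrides) -> FemurSpec:
    return replace(FemurSpec(), **overrides)


@dataclass
class GroundTruth:
    """Exact construction-frame anatomy of a generated femur."""

    landmarks: dict  # name -> (3,) point: FHC MEC LEC MPC LPC PTC ICN SGT LT
    axes: dict       # name -> Line3: shaft, neck, PFEA
    planes: dict     # name -> Plane3: TTP (normal points posterior)
    neck_base: np.ndarray
    ccd_angle: float
    version_angle: float
    neck_length: float
    side: str
    condyles: dict | None = None  # medial/lateral -> center, axes rows, radii

    def transformed(self, T: RigidTransform) -> "GroundTruth":
        condyles = None
        if self.condyles is not None:
            condyles = {k: {"center": T.apply(v["center"]),
                            "axes": v["axes"] @ T.rotation.T,
                            "radii": np.asarray(v["radii"], dtype=float)}
                        for k, v in self.condyles.items()}
        return GroundTruth(
            landmarks={k: T.apply(v) for k, v in self.landmarks.items()},
            axes={k: v.transformed(T) for k, v in self.axes.items()},
            planes={k: v.transformed(T) for k, v in self.planes.items()},
            neck_base=T.apply(self.neck_base),
            ccd_angle=self.ccd_angle, version_angle=self.version_angle,
            neck_length=self.neck_length, side=self.side, condyles=condyles)

    def mirrored_y(self) -> "GroundTruth":
        m = np.array([1.0, -1.0, 1.0])

        def mir_line(l: Line3) -> Line3:
            return Line3(l.point * m, unit(l.direction * m))

        def mir_plane(p: Plane3) -> Plane3:
            return Plane3(p.point * m, unit(p.normal * m))

        condyles = None
        if self.condyles is not None:
            condyles = {k: {"center": v["center"] * m,
                            "axes": v["axes"] * m,
                            "radii": np.asarray(v["radii"], dtype=float)}
                        for k, v in self.condyles.items()}
        return GroundTruth(
            landmarks={k: v * m for k, v in self.landmarks.items()},
            axes={k: mir_line(v) for k, v in self.axes.items()},
            planes={k: mir_plane(v) for k, v in self.planes.items()},
            neck_base=self.neck_base * m,
            ccd_angle=self.ccd_angle, version_angle=self.version_angle,
            neck_length=self.neck_length,
            side="left" if self.side == "right" else "right", condyles=condyles)


# ------------------------------------------------------------------ implicit

def _sd_sphere(p, center, r):
    return np.linalg.norm(p - center, axis=1) - r


def _sd_capsule(p, a, b, r):
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[:, None] * ab), axis=1) - r


def _sd_polyline(p, pts, r):
    """Union of capsules along a polyline; ``r`` may be scalar or per-vertex
    (segments use the mean of their endpoint radii)."""
    radii = np.broadcast_to(np.asarray(r, dtype=float), (len(pts),))
    d = None
    for a, b, ra, rb in zip(pts[:-1], pts[1:], radii[:-1], radii[1:]):
        dk = _sd_capsule(p, a, b, 0.5 * (ra + rb))
        d = dk if d is None else np.minimum(d, dk)
    return d


def _sd_ellipsoid(p, center, axes_rows, radii):
    """Approximate signed distance to an ellipsoid (exact zero set)."""
    q = (p - center) @ np.asarray(axes_rows).T / np.asarray(radii)
    return (np.linalg.norm(q, axis=1) - 1.0) * float(np.min(radii))


def _smin(a, b, k):
    """Polynomial smooth min; exact min when |a - b| >= k."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b * (1.0 - h) + a * h - k * h * (1.0 - h)


def _smax(a, b, k):
    return -_smin(-a, -b, k)


class _Construction:
    """Derived geometry of the canonical (right) construction frame."""

    def __init__(self, spec: FemurSpec):
        s = spec
        L = s.total_length
        a_rad = np.deg2rad(180.0 - s.ccd_angle)
        v_rad = np.deg2rad(s.version_angle)
        self.neck_dir = np.array([
            np.cos(a_rad),
            -np.sin(a_rad) * np.cos(v_rad),   # medial is -y
            np.sin(a_rad) * np.sin(v_rad),    # anteversion tilts anteriorly
        ])
        self.neck_base = np.array([
            L / 2.0 - s.head_radius - s.neck_length * np.cos(a_rad), 0.0, 0.0])
        self.fhc = self.neck_base + s.neck_length * self.neck_dir
        self.neck_radius = 0.5 * s.head_radius

        # condyles: prolate spheroids, major axis along the posterior-distal
        # diagonal so sagittal sections are true ellipses with stable foci
        self.condyle_dpd = unit([-1.0, 0.0, -1.0])
        self.condyle_e3 = np.cross(self.condyle_dpd, [0.0, 1.0, 0.0])
        r_cm, r_cl = s.condyle_radius_medial, s.condyle_radius_lateral
        r1m, r1l = r_cm + s.condyle_elongation, r_cl + s.condyle_elongation
        h_m = np.sqrt((r1m ** 2 + r_cm ** 2) / 2.0)  # support along -z (and -x)
        h_l = np.sqrt((r1l ** 2 + r_cl ** 2) / 2.0)
        r_cmax = max(r_cm, r_cl)
        self.z_ttp = -(r_cmax + 8.0)
        self.x_c = -L / 2.0 + max(h_m, h_l)
        half = s.condyle_separation / 2.0
        self.c_med = np.array([self.x_c, -half, self.z_ttp + h_m])
        self.c_lat = np.array([self.x_c, +half, self.z_ttp + h_l])
        self.condyle_axes = np.stack([self.condyle_dpd, [0.0, 1.0, 0.0], self.condyle_e3])
        self.condyle_radii_med = np.array([r1m, r_cm, r_cm])
        self.condyle_radii_lat = np.array([r1l, r_cl, r_cl])
        self.h_med, self.h_lat = h_m, h_l
        # posterior tangency points (support points of the spheroids along -z)
        self.mpc = np.array([self.x_c - (r1m ** 2 - r_cm ** 2) / (2 * h_m),
                             -half, self.z_ttp])
        self.lpc = np.array([self.x_c - (r1l ** 2 - r_cl ** 2) / (2 * h_l),
                             +half, self.z_ttp])

        # trochlear bridge: capsule along a centerline that bows proximally
        # toward the midline, giving the frontal outline a distinct notch peak
        self.trochlea_r = 16.0
        self.trochlea_vee = 0.0        # straight ridge: exact crease ground truth
        self.trochlea_vee_width = 12.0  # half-width of the V profile
        self.x_t = self.x_c + 12.0
        self.z_t = self.z_ttp + r_cmax + 10.0
        ty = np.linspace(-half, half, 17)
        bow = self.trochlea_vee * np.maximum(0.0, 1.0 - np.abs(ty) / self.trochlea_vee_width)
        self.trochlea_polyline = np.column_stack([
            self.x_t + bow, ty, np.full_like(ty, self.z_t)])

        self.carve_center = np.array([self.x_c, 0.0, self.z_ttp + 10.0])
        self.carve_r = 12.0 + s.groove_depth

        self.shaft_a = np.array([self.x_c + 38.0, 0.0, 0.0])
        self.shaft_b = self.neck_base.copy()
        self.meta_r = min(s.shaft_radius + 1.0, 15.0)
        self.meta_a = self.shaft_a.copy()
        self.meta_b = np.array([self.x_t + 6.0, 0.0, self.z_t + 6.0])

        self.ec_r = 8.0
        apex_m = half + r_cm + s.epicondyle_offset
        apex_l = half + r_cl + s.epicondyle_offset
        self.ec_med_center = np.array([self.x_c, -(apex_m - self.ec_r), self.c_med[2]])
        self.ec_lat_center = np.array([self.x_c, +(apex_l - self.ec_r), self.c_lat[2]])
        self.mec = np.array([self.x_c, -apex_m, self.c_med[2]])
        self.lec = np.array([self.x_c, +apex_l, self.c_lat[2]])

        self.gt_r = 17.0
        self.gt_center = np.array([
            self.neck_base[0] + s.trochanter_height_greater - self.gt_r, 20.0, 0.0])
        self.sgt = self.gt_center + np.array([self.gt_r, 0.0, 0.0])

        self.lt_r = 10.0
        self.lt_center = self.neck_base + np.array([-s.trochanter_height_lesser, -12.0, -10.0])
        lt_out = unit([0.0, -12.0, -10.0])
        self.lt = self.lt_center + self.lt_r * lt_out

        self.ptc_r = 9.0
        self.ptc_center = np.array([self.neck_base[0] - 8.0, -6.0, self.z_ttp + self.ptc_r])
        self.ptc = np.array([self.ptc_center[0], self.ptc_center[1], self.z_ttp])

        # shaft bow: anterior quadratic offset, zero at both shaft ends;
        # slight fusiform (barrel) radius profile so the shaft segment is a
        # genuine ellipsoid for the shaft-axis fit (a perfect cylinder makes
        # the quadric degenerate)
        n_seg = 32
        t = np.linspace(0.0, 1.0, n_seg + 1)
        line = self.shaft_a + t[:, None] * (self.shaft_b - self.shaft_a)
        line[:, 2] += s.shaft_bow * (1.0 - (2.0 * t - 1.0) ** 2)
        self.shaft_polyline = line
        self.shaft_radii = s.shaft_radius * (1.0 + 0.10 * (1.0 - (2.0 * t - 1.0) ** 2))
        self.spec = s

        self.icn = self._icn_point()

    def _icn_point(self) -> np.ndarray:
        """Crease of trochlea circle and carve circle in the y=0 sagittal
        plane: the anterior-proximal intersection is the groove boundary."""
        tc = np.array([self.x_t + self.trochlea_vee, self.z_t])
        fc = np.array([self.carve_center[0], self.carve_center[2]])
        rt, rf = self.trochlea_r, self.carve_r
        d = np.linalg.norm(fc - tc)
        if not abs(rt - rf) < d < rt + rf:
            raise GenerationError("groove carve does not intersect the trochlea")
        a = (d * d + rt * rt - rf * rf) / (2.0 * d)
        h = np.sqrt(max(rt * rt - a * a, 0.0))
        u = (fc - tc) / d
        base = tc + a * u
        perp = np.array([-u[1], u[0]])
        p1, p2 = base + h * perp, base - h * perp
        pick = p1 if p1[1] > p2[1] else p2  # larger z: anterior crease
        return np.array([pick[0], 0.0, pick[1]])

    def field(self, p: np.ndarray) -> np.ndarray:
        """Signed field, negative inside; exact SDF away from blends."""
        s = self.spec
        k = _BLEND
        parts = [
            _sd_sphere(p, self.fhc, s.head_radius),
            _sd_capsule(p, self.neck_base, self.fhc, self.neck_radius),
            _sd_polyline(p, self.shaft_polyline, self.shaft_radii),
            _sd_capsule(p, self.meta_a, self.meta_b, self.meta_r),
            _sd_polyline(p, self.trochlea_polyline, self.trochlea_r),
            _sd_ellipsoid(p, self.c_med, self.condyle_axes, self.condyle_radii_med),
            _sd_ellipsoid(p, self.c_lat, self.condyle_axes, self.condyle_radii_lat),
            _sd_sphere(p, self.ec_med_center, self.ec_r),
            _sd_sphere(p, self.ec_lat_center, self.ec_r),
            _sd_sphere(p, self.gt_center, self.gt_r),
            _sd_sphere(p, self.lt_center, self.lt_r),
            _sd_sphere(p, self.ptc_center, self.ptc_r),
        ]
        f = parts[0]
        for g in parts[1:]:
            f = _smin(f, g, k)
        carve = _sd_sphere(p, self.carve_center, self.carve_r)
        return _smax(f, -carve, 0.8)  # sharper crease at the groove boundary

    def ground_truth(self) -> GroundTruth:
        s = self.spec
        shaft_mid = 0.5 * (self.shaft_a + self.shaft_b)
        gt = GroundTruth(
            landmarks={
                "FHC": self.fhc.copy(),
                "MEC": self.mec.copy(), "LEC": self.lec.copy(),
                "MPC": self.mpc.copy(),
                "LPC": self.lpc.copy(),
                "PTC": self.ptc.copy(),
                "ICN": self.icn.copy(),
                "SGT": self.sgt.copy(), "LT": self.lt.copy(),
            },
            axes={
                "shaft": Line3(shaft_mid, np.array([1.0, 0.0, 0.0])),
                "neck": Line3(self.neck_base.copy(), self.neck_dir.copy()),
                "PFEA": Line3(0.5 * (self.c_med + self.c_lat),
                              unit(self.c_lat - self.c_med)),
            },
            planes={
                "TTP": Plane3(np.array([self.x_c, 0.0, self.z_ttp]),
                              np.array([0.0, 0.0, -1.0])),
            },
            neck_base=self.neck_base.copy(),
            ccd_angle=s.ccd_angle, version_angle=s.version_angle,
            neck_length=s.neck_length, side="right",
            condyles={
                "medial": {"center": self.c_med.copy(),
                           "axes": self.condyle_axes.copy(),
                           "radii": self.condyle_radii_med.copy()},
                "lateral": {"center": self.c_lat.copy(),
                            "axes": self.condyle_axes.copy(),
                            "radii": self.condyle_radii_lat.copy()},
            })
        return gt


def _extract_mesh(con: _Construction, pitch: float, subdivisions: int) -> SurfaceMesh:
    pts = np.concatenate([
        con.shaft_polyline, [con.fhc, con.c_med, con.c_lat, con.meta_b,
                             con.trochlea_polyline[0], con.trochlea_polyline[4],
                             con.trochlea_polyline[-1], con.gt_center,
                             con.lt_center, con.ptc_center,
                             con.ec_med_center, con.ec_lat_center]])
    rmax = max(con.spec.head_radius, con.gt_r, con.trochlea_r,
               con.spec.condyle_radius_medial, con.spec.condyle_radius_lateral)
    lo = pts.min(axis=0) - rmax - 3 * pitch
    hi = pts.max(axis=0) + rmax + 3 * pitch
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    xs = lo[0] + pitch * np.arange(shape[0])
    ys = lo[1] + pitch * np.arange(shape[1])
    zs = lo[2] + pitch * np.arange(shape[2])
    vol = np.empty(shape, dtype=np.float32)
    # evaluate slab-wise to bound memory
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    flat_yz = np.column_stack([yy.ravel(), zz.ravel()])
    for i, x in enumerate(xs):
        q = np.column_stack([np.full(len(flat_yz), x), flat_yz])
        vol[i] = con.field(q).reshape(shape[1], shape[2]).astype(np.float32)
    if vol.min() >= 0 or vol.max() <= 0:
        raise GenerationError("implicit surface does not cross zero on the grid")
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts.astype(float) + lo
    faces = np.ascontiguousarray(faces[:, ::-1])  # outward for negative-inside
    verts = _project_to_surface(con, verts)
    for _ in range(max(int(subdivisions), 0)):
        verts, faces = _subdivide_once(verts, faces)
        verts = _project_to_surface(con, verts)
    mesh = SurfaceMesh(verts, faces, clean=True)
    if signed_volume(mesh) < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1], clean=False)
    if not mesh.is_closed:
        raise GenerationError("generated surface is not closed; refine voxel_pitch")
    return mesh


def _project_to_surface(con: _Construction, verts: np.ndarray, iters: int = 3) -> np.ndarray:
    h = 0.05
    v = verts.copy()
    for _ in range(iters):
        f0 = con.field(v)
        g = np.empty_like(v)
        for ax in range(3):
            dv = np.zeros(3)
            dv[ax] = h
            g[:, ax] = (con.field(v + dv) - con.field(v - dv)) / (2 * h)
        norm2 = np.einsum("ij,ij->i", g, g)
        norm2[norm2 < 1e-12] = 1.0
        v = v - (f0 / norm2)[:, None] * g
    return v


def _subdivide_once(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    uniq, inv = np.unique(np.sort(edges, axis=1), axis=0, return_inverse=True)
    mids = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    mid = inv.reshape(3, -1).T + len(v)
    a, b, c = f[:, 0], f[:, 1], f[:, 2]
    ab, bc, ca = mid[:, 0], mid[:, 1], mid[:, 2]
    nf = np.concatenate([
        np.stack([a, ab, ca], axis=1), np.stack([b, bc, ab], axis=1),
        np.stack([c, ca, bc], axis=1), np.stack([ab, bc, ca], axis=1)])
    return np.concatenate([v, mids]), nf


def generate_femur(spec: FemurSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Generate a closed femur-like mesh and its exact ground truth.

    The ground truth is computed analytically from the construction. For
    ``side='left'`` the canonical right-side construction is mirrored across
    the x-z plane (landmarks and axes mirror exactly).
    """
    spec.validate()
    con = _Construction(spec)
    mesh = _extract_mesh(con, spec.voxel_pitch, spec.subdivisions)
    gt = con.ground_truth()
    if spec.side == "left":
        mesh = mesh.mirrored(axis=1)
        gt = gt.mirrored_y()
    return mesh, gt
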