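"""Stage 2: a-priori-knowledge refinement of landmarks, axes and planes.

All operations run in the canonical pose produced by stage 1 (right-side
anatomy; x distal-/proximal+, y medial-/lateral+, z posterior-/anterior+).
Left femora are mirrored to this pose before stage 1 and the results are
mirrored back afterwards, so this module is side-agnostic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from .config import DetectConfig
from .errors import DegenerateFitError, MeshError, StageError
from .mesh import SurfaceMesh
from .primitives import fit_ellipse_3d, fit_ellipsoid, fit_line_3d, fit_sphere
from .sections import (Ball, HalfSpace, clip_mesh, cut_mesh_with_plane,
                       intersect_line_mesh, silhouette)
from .transforms import Line3, Plane3, rotation_about_axis, unit

_POSTERIOR = np.array([0.0, 0.0, -1.0])
_PROXIMAL = np.array([1.0, 0.0, 0.0])
_LATERAL = np.array([0.0, 1.0, 0.0])


@dataclass
class AnatomyResult:
    """Detected anatomy: named landmarks, axes, planes and diagnostics."""

    landmarks: dict = field(default_factory=dict)  # name -> (3,)
    axes: dict = field(default_factory=dict)       # name -> Line3
    planes: dict = field(default_factory=dict)     # name -> Plane3
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "landmarks": {k: [float(x) for x in v] for k, v in self.landmarks.items()},
            "axes": {k: {"point": [float(x) for x in v.point],
                         "direction": [float(x) for x in v.direction]}
                     for k, v in self.axes.items()},
            "planes": {k: {"point": [float(x) for x in v.point],
                           "normal": [float(x) for x in v.normal]}
                       for k, v in self.planes.items()},
            "diagnostics": self.diagnostics,
        }


def _argextreme(points: np.ndarray, direction: np.ndarray) -> int:
    """Index of the extreme point along ``direction``; deterministic
    tie-break by smallest index after 1e-9 rounding."""
    s = np.round(points @ direction, 9)
    return int(np.argmax(s))


# ------------------------------------------------------------------ FHC

def refine_fhc(head_points, min_points: int = 50) -> tuple[np.ndarray, float, dict]:
    """Femoral head center: least-squares sphere fit to the mapped head."""
    p = np.asarray(head_points, dtype=float).reshape(-1, 3)
    if len(p) < min_points:
        raise StageError("fhc", f"need >= {min_points} head vertices, got {len(p)}")
    try:
        f = fit_sphere(p)
    except DegenerateFitError as exc:
        raise StageError("fhc", str(exc)) from exc
    diag = {"radius": f.radius, "rms_residual": f.rms_residual,
            "algebraic_rms": f.algebraic_rms, "n_points": len(p),
            "degraded": f.rms_residual > 1.0}
    return f.center, f.radius, diag


# ------------------------------------------------------------- shaft axis

def detect_shaft_axis(mesh: SurfaceMesh, fhc, config: DetectConfig | None = None
                      ) -> tuple[Line3, dict]:
    """Shaft axis: mesh diameter defines the resection normal, the middle
    half of the bone is kept and an ellipsoid is fitted; its major axis,
    oriented proximally (toward the FHC end), is the shaft axis.
    """
    cfg = config or DetectConfig()
    fhc = np.asarray(fhc, dtype=float)
    hull = ConvexHull(mesh.vertices)
    hv = mesh.vertices[hull.vertices]
    # mesh diameter among hull vertices
    i, j = _max_pairwise(hv)
    p, q = hv[i], hv[j]
    d = unit(q - p)
    if np.dot(d, fhc - 0.5 * (p + q)) < 0:  # orient proximally using the FHC
        p, q = q, p
        d = -d
    L = float(np.linalg.norm(q - p))
    lo, hi = cfg.shaft_keep_fraction
    shaft = clip_mesh(mesh, HalfSpace(Plane3(p + lo * L * d, d)))
    shaft = clip_mesh(shaft, HalfSpace(Plane3(p + hi * L * d, -d)))
    # sample vertices and face centroids: coarse meshes can leave all crop
    # vertices on the two cut rings, which do not determine the quadric
    pts = np.concatenate([shaft.vertices, shaft.triangles().mean(axis=1)])
    if len(pts) > 4000:  # plenty for a 9-parameter fit
        pts = pts[np.linspace(0, len(pts) - 1, 4000).astype(int)]
    try:
        ell = fit_ellipsoid(pts)
    except DegenerateFitError as exc:
        raise StageError("shaft_axis", str(exc)) from exc
    axis_dir = ell.major_axis if np.dot(ell.major_axis, d) >= 0 else -ell.major_axis
    diag = {"diameter_mm": L, "ellipsoid_radii": [float(r) for r in ell.radii],
            "kept_vertices": shaft.n_vertices}
    return Line3(ell.center, unit(axis_dir)), diag


def _max_pairwise(points: np.ndarray) -> tuple[int, int]:
    n = len(points)
    best = (0, 0, -1.0)
    block = 512
    for a in range(0, n, block):
        pa = points[a:a + block]
        d2 = ((pa[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        k = np.argmax(d2)
        i, j = divmod(k, n)
        if d2[i, j] > best[2]:
            best = (a + i, j, d2[i, j])
    return best[0], best[1]


# -------------------------------------------------------------- neck axis

def refine_neck_axis(mesh: SurfaceMesh, neck_points, fhc,
                     config: DetectConfig | None = None) -> tuple[Line3, dict]:
    """Neck axis by iterative minimization of the cutting-contour perimeter.

    The initial axis is the normal of an ellipse fitted to the mapped neck
    area; the cutting-plane orientation (two tilt angles) and its offset
    along the axis are then refined by coordinate descent until the minimal
    contour perimeter converges.
    """
    cfg = config or DetectConfig()
    fhc = np.asarray(fhc, dtype=float)
    p = np.asarray(neck_points, dtype=float).reshape(-1, 3)
    if len(p) < 6:
        raise StageError("neck_axis", "mapped neck region too small")
    try:
        ell = fit_ellipse_3d(p)
    except DegenerateFitError as exc:
        raise StageError("neck_axis", str(exc)) from exc
    c0 = ell.center
    n0 = ell.normal if np.dot(ell.normal, fhc - ell.center) >= 0 else -ell.normal

    # restrict cutting to a neighborhood of the neck for speed and to avoid
    # distant contours
    spread = float(np.linalg.norm(p - c0, axis=1).max())
    ball_r = max(45.0, 2.0 * spread + 20.0)
    centroids = mesh.triangles().mean(axis=1)
    near = np.linalg.norm(centroids - c0, axis=1) <= ball_r
    sub = mesh.submesh(near)

    def perimeter(n, t):
        plane = Plane3(c0 + t * n0, n)
        contours = [c for c in cut_mesh_with_plane(sub, plane) if c.closed]
        if not contours:
            return None, None
        line = Line3(c0, n)
        best = min(contours, key=lambda c: line.distance_to_point(c.centroid))
        return best.perimeter, best

    n = n0
    t = 0.0
    val, contour = perimeter(n, t)
    if val is None:
        raise StageError("neck_axis", "no neck-containing cutting contour found")
    history = [val]
    it = 0
    for step in cfg.neck_angle_steps_deg:
        toff = cfg.neck_offset_step_mm * step / cfg.neck_angle_steps_deg[0]
        improved = True
        while improved and it < cfg.neck_max_iterations:
            improved = False
            u1 = unit(np.cross(n, [0.0, 0.0, 1.0] if abs(n[2]) < 0.9 else [0.0, 1.0, 0.0]))
            u2 = np.cross(n, u1)
            for cand_n, cand_t in (
                    (rotation_about_axis(u1, step) @ n, t),
                    (rotation_about_axis(u1, -step) @ n, t),
                    (rotation_about_axis(u2, step) @ n, t),
                    (rotation_about_axis(u2, -step) @ n, t),
                    (n, t + toff), (n, t - toff)):
                it += 1
                v, c = perimeter(unit(cand_n), cand_t)
                if v is not None and v < val - cfg.neck_tol_mm:
                    n, t, val, contour = unit(cand_n), cand_t, v, c
                    history.append(val)
                    improved = True
                    break
    degraded = it >= cfg.neck_max_iterations
    center = contour.centroid
    direction = n if np.dot(n, fhc - center) >= 0 else -n
    diag = {"perimeter_history": history, "iterations": it,
            "final_perimeter": val, "degraded": degraded,
            "initial_normal": [float(x) for x in n0]}
    return Line3(center, unit(direction)), diag


# ------------------------------------------------------------- table top

def detect_ttp(mesh: SurfaceMesh, medial_condyle_pts, lateral_condyle_pts,
               neck_axis: Line3, config: DetectConfig | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, Plane3, dict]:
    """MPC, LPC, PTC and the table top plane by fixed-point iteration.

    Three parts are used: the two condyle regions and the proximal part with
    the head resected at the neck. The most posterior point of each part (in
    the current frame) defines a temporary plane; the parts are re-oriented
    into that plane's frame until the update rotation reaches identity.
    """
    cfg = config or DetectConfig()
    med = np.asarray(medial_condyle_pts, dtype=float).reshape(-1, 3)
    lat = np.asarray(lateral_condyle_pts, dtype=float).reshape(-1, 3)
    v = mesh.vertices
    x = v[:, 0]
    cut = x.min() + (1.0 - cfg.ttp_proximal_fraction) * (x.max() - x.min())
    prox_mask = x >= cut
    # resect the head: drop the FHC side of the plane through the neck isthmus
    head_side = (v - neck_axis.point) @ neck_axis.direction
    prox_mask &= head_side <= 0
    prox = v[prox_mask]
    if len(prox) == 0:
        raise StageError("ttp", "proximal part is empty after head resection")

    parts = (med, lat, prox)
    R = np.eye(3)
    n_iter = 0
    converged = False
    for n_iter in range(1, cfg.ttp_max_iterations + 1):
        pts = [part @ R.T for part in parts]
        picks = [_argextreme(pp, _POSTERIOR) for pp in pts]
        mpc, lpc, ptc = (pts[k][picks[k]] for k in range(3))
        normal = np.cross(lpc - mpc, ptc - mpc)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            raise StageError("ttp", "degenerate (collinear) contact points")
        normal = normal / nn
        if normal @ _POSTERIOR < 0:
            normal = -normal
        e_ant = -normal
        ml = lpc - mpc
        ml = unit(ml - (ml @ e_ant) * e_ant)
        e_dp = np.cross(ml, e_ant)
        Ru = np.stack([e_dp, ml, e_ant])  # maps current coords -> TTP frame
        ang = np.arccos(np.clip((np.trace(Ru) - 1.0) / 2.0, -1.0, 1.0))
        R = Ru @ R
        if ang < cfg.ttp_rotation_tol_rad:
            converged = True
            break
    # transport the fixed-point picks back to the input frame
    mpc_w, lpc_w, ptc_w = (parts[k][_argextreme(parts[k] @ R.T, _POSTERIOR)]
                           for k in range(3))
    normal = np.cross(lpc_w - mpc_w, ptc_w - mpc_w)
    normal = unit(normal)
    if normal @ _POSTERIOR < 0:
        normal = -normal
    plane = Plane3(mpc_w, normal)
    diag = {"iterations": n_iter, "converged": converged,
            "degraded": not converged}
    return mpc_w, lpc_w, ptc_w, plane, diag


# ------------------------------------------------------------------- USP

def compute_usp(distal: SurfaceMesh, medial_condyle_pts, lateral_condyle_pts,
                config: DetectConfig | None = None
                ) -> tuple[Plane3, Line3, Line3, dict]:
    """Unified sagittal plane of the condyles.

    For a candidate sagittal direction, each condyle is cut with a stack of
    parallel planes; an ellipse is fitted to the articulating
    (posterior-distal) arc of each contour. The direction is optimized until
    the dispersion of the posterior foci about their best-fit line is
    minimal. PFEA passes through the posterior foci, CEA through the ellipse
    centers, and the USP is normal to the optimal cutting direction.
    """
    cfg = config or DetectConfig()
    regions = [np.asarray(medial_condyle_pts, dtype=float).reshape(-1, 3),
               np.asarray(lateral_condyle_pts, dtype=float).reshape(-1, 3)]
    # cut only the neighborhood of each condyle; the posterior-distal arc is
    # local, so open chains at the neighborhood boundary are acceptable
    submeshes = []
    centroids_f = distal.triangles().mean(axis=1)
    for reg in regions:
        c = reg.mean(axis=0)
        spread = float(np.linalg.norm(reg - c, axis=1).max())
        near = np.linalg.norm(centroids_f - c, axis=1) <= 1.6 * spread + 15.0
        if not near.any():
            raise StageError("usp", "a condyle region has no nearby surface")
        submeshes.append(distal.submesh(near))

    def evaluate(a_deg, b_deg, collect=False):
        u = rotation_about_axis([0, 0, 1], a_deg) @ rotation_about_axis([1, 0, 0], b_deg) \
            @ _LATERAL
        foci, centers = [], []
        for reg, sub in zip(regions, submeshes):
            t = reg @ u
            lo, hi = np.quantile(t, cfg.usp_plane_span)
            offsets = np.linspace(lo, hi, cfg.usp_planes_per_condyle)
            reg_centroid = reg.mean(axis=0)
            n_ok = 0
            for off in offsets:
                plane = Plane3(off * u, u)
                contours = [c for c in cut_mesh_with_plane(sub, plane)
                            if len(c.points) >= 10]
                if not contours:
                    continue
                target = reg_centroid + (off - reg_centroid @ u) * u
                cont = min(contours, key=lambda c: np.linalg.norm(c.centroid - target))
                if np.linalg.norm(cont.centroid - target) > 30.0:
                    continue
                arc = _articulating_arc(cont, cfg.usp_arc_half_angle_deg)
                if len(arc) < 8:
                    continue
                try:
                    ell = fit_ellipse_3d(arc)
                except DegenerateFitError:
                    continue
                f1, f2 = ell.foci
                foci.append(f1 if f1[2] <= f2[2] else f2)  # posterior focus
                centers.append(ell.center)
                n_ok += 1
            if n_ok < 2:
                return None, None, None
        foci = np.asarray(foci)
        centers = np.asarray(centers)
        cpt, cdir = fit_line_3d(foci)
        resid = foci - cpt
        resid = resid - np.outer(resid @ cdir, cdir)
        disp = float((resid ** 2).sum())
        if collect:
            return disp, foci, centers
        return disp, None, None

    a = b = 0.0
    val, _, _ = evaluate(a, b)
    if val is None:
        raise StageError("usp", "fewer than 2 valid contours per condyle")
    history = [val]
    it = 0
    for step in cfg.usp_angle_steps_deg:
        improved = True
        while improved and it < cfg.usp_max_iterations:
            improved = False
            for da, db in ((step, 0), (-step, 0), (0, step), (0, -step)):
                it += 1
                v2, _, _ = evaluate(a + da, b + db)
                if v2 is not None and v2 < val - cfg.usp_tol:
                    a, b, val = a + da, b + db, v2
                    history.append(val)
                    improved = True
                    break
    disp, foci, centers = evaluate(a, b, collect=True)
    u = rotation_about_axis([0, 0, 1], a) @ rotation_about_axis([1, 0, 0], b) @ _LATERAL
    if u @ _LATERAL < 0:  # orient lateral-positive in the canonical pose
        u = -u
    fpt, fdir = fit_line_3d(foci)
    cpt, cdir = fit_line_3d(centers)
    if fdir @ u < 0:
        fdir = -fdir
    if cdir @ u < 0:
        cdir = -cdir
    pfea = Line3(fpt, fdir)
    cea = Line3(cpt, cdir)
    usp = Plane3(fpt, u)
    diag = {"dispersion_history": history, "iterations": it,
            "final_dispersion": disp, "angles_deg": [a, b],
            "n_foci": int(len(foci))}
    return usp, pfea, cea, diag


def _articulating_arc(contour, half_angle_deg: float) -> np.ndarray:
    """Posterior-distal arc of a closed sagittal contour."""
    pts = contour.points
    c = pts.mean(axis=0)
    d = pts - c
    # in-plane posterior-distal diagonal
    diag = -_PROXIMAL + _POSTERIOR  # (-1, 0, -1)
    n = contour.plane.normal
    diag = diag - (diag @ n) * n
    nd = np.linalg.norm(diag)
    if nd < 1e-9:
        return pts[:0]
    diag = diag / nd
    dn = np.linalg.norm(d, axis=1)
    cosang = (d @ diag) / np.maximum(dn, 1e-12)
    return pts[cosang >= np.cos(np.deg2rad(half_angle_deg))]


# ------------------------------------------------------------ epicondyles

def detect_epicondyles(distal: SurfaceMesh, ml_dir, cea: Line3,
                       mapped_mec, mapped_lec,
                       config: DetectConfig | None = None
                       ) -> tuple[np.ndarray, np.ndarray, dict]:
    """MEC and LEC by the three-candidate selection rule.

    Per side: EC_CEA (CEA-surface intersection), EC_max (extreme point along
    the USP mediolateral axis) and EC_map (mapped template epicondyle). If
    EC_map is closer to EC_CEA than EC_max is, the extreme point is
    recomputed on the sub-surface inside the two balls around EC_CEA and
    EC_map (osteophyte guard); otherwise EC_max is final.
    """
    cfg = config or DetectConfig()
    ml = unit(ml_dir)
    pts, _ = intersect_line_mesh(distal, cea)
    if len(pts) < 2:
        raise StageError("epicondyles", "CEA does not intersect the distal surface")
    out = {}
    diag = {}
    for name, sign, mapped in (("MEC", -1.0, mapped_mec), ("LEC", +1.0, mapped_lec)):
        s = pts @ (sign * ml)
        ec_cea = pts[int(np.argmax(np.round(s, 9)))]
        ec_max = distal.vertices[_argextreme(distal.vertices, sign * ml)]
        ec_map = np.asarray(mapped, dtype=float)
        d_map = float(np.linalg.norm(ec_cea - ec_map))
        d_max = float(np.linalg.norm(ec_cea - ec_max))
        if d_map < d_max:
            # EC_CEA (on the surface) and EC_map (a surface vertex) belong to
            # the clipped part by construction; the ball clips can miss when
            # the radius is below the mesh resolution
            candidates = [ec_cea[None, :], ec_map[None, :]]
            for center in (ec_cea, ec_map):
                try:
                    clipped = clip_mesh(distal, Ball(center, d_map))
                except MeshError:
                    continue
                candidates.append(clipped.vertices)
            cand = np.concatenate(candidates)
            final = cand[_argextreme(cand, sign * ml)]
            branch = "clipped"
        else:
            final = ec_max
            branch = "ec_max"
        out[name] = final
        diag[name] = {"branch": branch, "d_cea_map": d_map, "d_cea_max": d_max,
                      "ec_cea": [float(v) for v in ec_cea],
                      "ec_max": [float(v) for v in ec_max]}
    return out["MEC"], out["LEC"], diag


# -------------------------------------------------------------------- ICN

def detect_icn(distal: SurfaceMesh, pfea: Line3,
               config: DetectConfig | None = None) -> tuple[np.ndarray, dict]:
    """Intercondylar notch landmark.

    The PFEA's surface crossings bound the intercondylar sector. Sagittal
    contours of the sector carry curvature-extreme boundary points between
    the trochlear surface and the fossa; the temporary landmark combines the
    median posteroanterior coordinate of those points with the local maximum
    of the distal outline of the frontal silhouette; the nearest boundary
    point is the final ICN.
    """
    cfg = config or DetectConfig()
    u = pfea.direction if pfea.direction @ _LATERAL >= 0 else -pfea.direction
    line = Line3(pfea.point, u)
    _, ts = intersect_line_mesh(distal, line)
    if len(ts) < 2:
        raise StageError("icn", "PFEA does not intersect the condyles")
    # interval around the line's midpoint where the line is outside the mesh
    gap = _outside_gap_near_zero(ts)
    if gap is None:
        raise StageError("icn", "no intercondylar gap found along the PFEA")
    a, b = gap
    w = b - a
    a += cfg.icn_slab_margin * w
    b -= cfg.icn_slab_margin * w
    sector = clip_mesh(distal, HalfSpace(Plane3(line.at(a), u)))
    sector = clip_mesh(sector, HalfSpace(Plane3(line.at(b), -u)))

    boundary = []
    offsets = np.linspace(a + 0.05 * w, b - 0.05 * w, cfg.icn_planes)
    for off in offsets:
        plane = Plane3(line.at(off), u)
        for cont in cut_mesh_with_plane(sector, plane):
            bp = _trochlea_fossa_boundary(cont, cfg.icn_curvature_window)
            if bp is not None:
                boundary.append(bp)
    if not boundary:
        raise StageError("icn", "no curvature extremum found in any contour")
    boundary = np.asarray(boundary)

    sil = silhouette(sector, [0.0, 0.0, 1.0])
    outline = np.concatenate([_densify_closed(c.points, 0.25) for c in sil])
    dp_temp, ml_temp = _distal_outline_peak(outline, cfg.icn_outline_bins)
    # posteroanterior component: median of the boundary points near the
    # outline peak (slab-edge creases belong to the condylar walls and would
    # bias a global median)
    near_peak = np.abs(boundary[:, 1] - ml_temp) <= max(3.0, 0.2 * w)
    sel = boundary[near_peak] if near_peak.sum() >= 3 else boundary
    pa_temp = float(np.median(sel[:, 2]))
    temp = np.array([dp_temp, ml_temp, pa_temp])
    final = boundary[int(np.argmin(np.linalg.norm(boundary - temp, axis=1)))]
    diag = {"n_boundary_points": int(len(boundary)),
            "boundary_points": [[float(x) for x in p] for p in boundary],
            "temporary_icn": [float(x) for x in temp],
            "sector_interval": [float(a), float(b)]}
    return final, diag


def _outside_gap_near_zero(ts: np.ndarray):
    """Largest between-crossings interval (line outside the mesh) nearest to
    parameter 0; crossing parity puts the outside on even interval indices
    when the line starts outside."""
    best = None
    for k in range(len(ts) - 1):
        # odd number of crossings passed -> inside the mesh
        if (k + 1) % 2 == 1:
            continue
        a, b = float(ts[k]), float(ts[k + 1])
        mid = 0.5 * (a + b)
        score = abs(mid)
        if best is None or score < best[0]:
            best = (score, (a, b))
    return None if best is None else best[1]


def _resample_polyline(pts: np.ndarray, closed: bool, ds: float) -> np.ndarray:
    """Uniform arc-length resampling (linear interpolation)."""
    if closed:
        pts = np.concatenate([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < ds * 4:
        return pts
    n = max(int(np.floor(total / ds)), 4)
    si = np.linspace(0.0, total, n, endpoint=not closed)
    out = np.empty((len(si), 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, pts[:, k])
    return out


def _curvature_series(contour, window: int, ds: float = 0.5):
    """Uniformly resampled contour with fixed-arc-scale curvature magnitude.

    Works for closed loops and open chains (curvature undefined at chain
    ends). Fixed arc scale makes the estimate robust to the irregular vertex
    spacing of extracted meshes.
    """
    pts = _resample_polyline(contour.points, contour.closed, ds)
    n = len(pts)
    w = max(int(window), 1)
    if n < 2 * w + 5:
        return None
    kappa = np.zeros(n)
    for i in range(n):
        if not contour.closed and (i < w or i >= n - w):
            continue
        kappa[i] = _three_point_curvature(pts[(i - w) % n], pts[i], pts[(i + w) % n])
    return pts, kappa


def _trochlea_fossa_boundary(contour, window: int, ds: float = 0.5,
                             kappa_min: float = 0.15,
                             max_walk_mm: float = 30.0):
    """Boundary point between the trochlear surface and the intercondylar
    fossa on one sagittal contour: the first concave curvature maximum
    encountered when walking posteriorly from the most distal contour point.
    Returns None when no such crease exists.
    """
    series = _curvature_series(contour, window, ds)
    if series is None:
        return None
    pts, kappa = series
    n = len(pts)
    w = max(int(window), 1)
    i0 = int(np.argmin(pts[:, 0]))  # most distal point
    # walking direction with decreasing z (posterior)
    ahead = pts[(i0 + np.arange(1, 6)) % n, 2].mean()
    behind = pts[(i0 - np.arange(1, 6)) % n, 2].mean()
    step = 1 if ahead < behind else -1
    max_steps = min(n - 1, int(max_walk_mm / ds))
    best = None
    for k in range(1, max_steps):
        i = (i0 + step * k) % n
        if not contour.closed and (i < w or i >= n - w):
            break
        if kappa[i] < kappa_min:
            continue
        prev_i, next_i = (i - 1) % n, (i + 1) % n
        if kappa[i] >= kappa[prev_i] and kappa[i] >= kappa[next_i]:
            lo = np.arange(i - w, i + w + 1) % n
            wts = np.maximum(kappa[lo] - 0.5 * kappa[i], 0.0)
            if wts.sum() <= 0:
                best = pts[i]
            else:
                est = (pts[lo] * wts[:, None]).sum(axis=0) / wts.sum()
                # keep the landmark on the contour (and thus on the surface)
                best = _project_to_polyline(est, pts[lo])
            break
    return best


def _project_to_polyline(q: np.ndarray, pts: np.ndarray) -> np.ndarray:
    best, dist = pts[0], np.inf
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom < 1e-18 else float(np.clip((q - a) @ ab / denom, 0.0, 1.0))
        p = a + t * ab
        d = float(np.linalg.norm(q - p))
        if d < dist:
            best, dist = p, d
    return best


def _three_point_curvature(p0, p1, p2) -> float:
    a = np.linalg.norm(p1 - p0)
    b = np.linalg.norm(p2 - p1)
    c = np.linalg.norm(p2 - p0)
    if a < 1e-12 or b < 1e-12 or c < 1e-12:
        return 0.0
    area2 = np.linalg.norm(np.cross(p1 - p0, p2 - p0))
    return float(2.0 * area2 / (a * b * c))


def _densify_closed(pts: np.ndarray, max_step: float) -> np.ndarray:
    """Resample a closed polyline so consecutive points are <= max_step apart."""
    out = []
    n = len(pts)
    for i in range(n):
        a, b = pts[i], pts[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(int(np.ceil(seg / max_step)), 1)
        t = np.arange(k) / k
        out.append(a + t[:, None] * (b - a))
    return np.concatenate(out)


def _distal_outline_peak(outline_pts: np.ndarray, bins: int) -> tuple[float, float]:
    """(x, y) of the local maximum of the distal (min-x) outline envelope.

    On a flat envelope plateau (near-cylindrical trochlea) the peak is taken
    at the center of the near-maximal bins for determinism.
    """
    # only the distal band matters; proximal cut edges of the sector would
    # otherwise masquerade as outline maxima
    depth = 45.0
    sel = outline_pts[:, 0] <= outline_pts[:, 0].min() + depth
    outline_pts = outline_pts[sel]
    y = outline_pts[:, 1]
    x = outline_pts[:, 0]
    edges = np.linspace(y.min(), y.max(), bins + 1)
    idx = np.clip(np.digitize(y, edges) - 1, 0, bins - 1)
    env = np.full(bins, np.nan)
    for b in range(bins):
        sel = idx == b
        if sel.any():
            env[b] = x[sel].min()
    valid = np.where(np.isfinite(env))[0]
    if len(valid) < 5:
        k = int(valid[len(valid) // 2])
        yc = 0.5 * (edges[k] + edges[k + 1])
        return float(env[k]), float(yc)
    # local maximum between the two condylar dips of the envelope
    mid = valid[len(valid) // 2]
    left = valid[valid <= mid]
    right = valid[valid >= mid]
    dip_l = int(left[np.argmin(env[left])])
    dip_r = int(right[np.argmin(env[right])])
    between_bins = valid[(valid >= dip_l) & (valid <= dip_r)]
    if len(between_bins) == 0:
        between_bins = valid
    vmax = np.max(env[between_bins])
    # plateau tolerant to small linear drift of the envelope: take the
    # center of the contiguous near-maximal interval
    near = between_bins[env[between_bins] >= vmax - 0.5]
    k = int(near[len(near) // 2])
    yc = 0.5 * (edges[k] + edges[k + 1])
    return float(env[k]), float(yc)


# ------------------------------------------------------------ passthrough

def passthrough_landmarks(mapped_landmarks: dict) -> tuple[np.ndarray, np.ndarray, dict]:
    """SGT and LT are taken from the mapping without refinement."""
    for name in ("SGT", "LT"):
        if name not in mapped_landmarks:
            raise StageError("passthrough", f"missing mapped landmark {name!r}")
    diag = {"mapped_only": ["SGT", "LT"]}
    return (np.asarray(mapped_landmarks["SGT"], dtype=float),
            np.asarray(mapped_landmarks["LT"], dtype=float), diag)
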