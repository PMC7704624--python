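"""Plane sections, region clipping and silhouettes of triangle meshes."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.ops import unary_union

from .errors import MeshError
from .mesh import SurfaceMesh
from .transforms import Plane3, unit

_ON_PLANE_EPS = 1e-12


@dataclass
class PlanarContour:
    """Polyline of 3D points lying in a plane.

    ``closed`` contours are loops (last point connects to first); open chains
    can occur when cutting meshes with boundaries. ``area`` is defined for
    closed contours only (0.0 otherwise).
    """

    points: np.ndarray  # (K, 3)
    plane: Plane3
    closed: bool = True
    perimeter: float = field(init=False)
    area: float = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.points = p
        seg = np.diff(p, axis=0)
        length = float(np.linalg.norm(seg, axis=1).sum())
        if self.closed and len(p) > 1:
            length += float(np.linalg.norm(p[0] - p[-1]))
        self.perimeter = length
        if self.closed and len(p) >= 3:
            u, v = self.plane.basis()
            q = p - self.plane.point
            x, y = q @ u, q @ v
            self.area = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)
        else:
            self.area = 0.0

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def max_plane_distance(self) -> float:
        return float(np.abs(self.plane.signed_distance(self.points)).max())


def cut_mesh_with_plane(mesh: SurfaceMesh, plane: Plane3) -> list[PlanarContour]:
    """Intersect a mesh with a plane.

    Returns one :class:`PlanarContour` per connected intersection component
    (closed loops on watertight regions, open chains where the cut runs into
    a mesh boundary). Empty list when the plane misses the mesh.
    """
    d = plane.signed_distance(mesh.vertices)
    # deterministic nudge for vertices exactly on the plane
    d = np.where(np.abs(d) < _ON_PLANE_EPS, _ON_PLANE_EPS, d)
    df = d[mesh.faces]
    crossing = (df.min(axis=1) < 0) & (df.max(axis=1) > 0)
    if not crossing.any():
        return []
    faces = mesh.faces[crossing]
    dfc = df[crossing]

    # for each crossing face, the two crossed edges (as sorted vertex pairs)
    segs = []  # (edge_key_a, edge_key_b) per face
    edge_pts: dict[tuple[int, int], np.ndarray] = {}
    V = mesh.vertices
    for tri, dv in zip(faces, dfc):
        keys = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            if (dv[a] < 0) != (dv[b] < 0):
                i, j = int(tri[a]), int(tri[b])
                key = (i, j) if i < j else (j, i)
                if key not in edge_pts:
                    t = d[key[0]] / (d[key[0]] - d[key[1]])
                    edge_pts[key] = V[key[0]] + t * (V[key[1]] - V[key[0]])
                keys.append(key)
        if len(keys) == 2:
            segs.append((keys[0], keys[1]))

    # walk segments into chains/loops
    adj: dict[tuple[int, int], list[int]] = {}
    for si, (a, b) in enumerate(segs):
        adj.setdefault(a, []).append(si)
        adj.setdefault(b, []).append(si)
    used = np.zeros(len(segs), dtype=bool)
    contours = []
    # open chains first (start at nodes of degree 1), then remaining loops
    starts = [k for k, v in adj.items() if len(v) == 1]
    for phase in (0, 1):
        nodes = starts if phase == 0 else list(adj.keys())
        for start in nodes:
            chain = _walk(start, segs, adj, used)
            if chain is None:
                continue
            keys, closed = chain
            pts = np.array([edge_pts[k] for k in keys])
            if len(pts) >= (3 if closed else 2):
                contours.append(PlanarContour(points=pts, plane=plane, closed=closed))
    contours.sort(key=lambda c: -c.perimeter)
    return contours


def _walk(start, segs, adj, used):
    avail = [si for si in adj.get(start, []) if not used[si]]
    if not avail:
        return None
    keys = [start]
    node = start
    si = avail[0]
    while True:
        used[si] = True
        a, b = segs[si]
        node = b if a == node else a
        if node == keys[0]:
            return keys, True
        keys.append(node)
        nxt = [sj for sj in adj.get(node, []) if not used[sj]]
        if not nxt:
            return keys, False
        si = nxt[0]


@dataclass(frozen=True)
class HalfSpace:
    """Kept region ``signed_distance >= 0`` of a plane."""
    plane: Plane3


@dataclass(frozen=True)
class Ball:
    """Kept region: inside the sphere of ``center`` and ``radius``."""
    center: np.ndarray
    radius: float


def clip_mesh(mesh: SurfaceMesh, region) -> SurfaceMesh:
    """Sub-mesh on the kept side of a region (half-space or ball).

    Faces crossing the region boundary are split at the boundary, so extreme
    point queries after clipping are not quantized to the input tessellation.
    The result may be open.
    """
    if isinstance(region, HalfSpace):
        f = region.plane.signed_distance
        crossing = _crossing_linear
    elif isinstance(region, Ball):
        c = np.asarray(region.center, dtype=float)
        r = float(region.radius)

        def f(p):
            return r - np.linalg.norm(np.atleast_2d(p) - c, axis=1)

        def crossing(p0, p1, f0, f1):
            return _sphere_crossing(p0, p1, c, r)
    else:
        raise MeshError(f"unsupported clip region {type(region).__name__}")

    d = np.asarray(f(mesh.vertices), dtype=float).reshape(-1)
    d = np.where(np.abs(d) < _ON_PLANE_EPS, _ON_PLANE_EPS, d)
    df = d[mesh.faces]
    inside = df > 0
    n_in = inside.sum(axis=1)
    keep_whole = mesh.faces[n_in == 3]
    mixed = np.where((n_in > 0) & (n_in < 3))[0]

    verts = [mesh.vertices]
    new_faces = [keep_whole]
    offset = mesh.n_vertices
    V = mesh.vertices
    for fi in mixed:
        tri = mesh.faces[fi]
        dv = df[fi]
        poly = []  # Sutherland-Hodgman on the triangle
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            da, db = dv[k], dv[(k + 1) % 3]
            if da > 0:
                poly.append(("v", int(a)))
            if (da > 0) != (db > 0):
                t = crossing(V[a], V[b], da, db)
                poly.append(("p", V[a] + t * (V[b] - V[a])))
        idx = []
        for kind, val in poly:
            if kind == "v":
                idx.append(val)
            else:
                verts.append(val[None, :])
                idx.append(offset)
                offset += 1
        for k in range(1, len(idx) - 1):
            new_faces.append(np.array([[idx[0], idx[k], idx[k + 1]]]))
    if len(new_faces) == 1 and len(keep_whole) == 0:
        raise MeshError("clip region removes the entire mesh")
    faces = np.concatenate([fb for fb in new_faces if len(fb)])
    if len(faces) == 0:
        raise MeshError("clip region removes the entire mesh")
    return SurfaceMesh(np.concatenate(verts), faces, clean=True)


def _crossing_linear(p0, p1, f0, f1):
    return f0 / (f0 - f1)


def _sphere_crossing(p0, p1, c, r):
    u = p1 - p0
    w = p0 - c
    a = u @ u
    b = 2.0 * (w @ u)
    cc = w @ w - r * r
    disc = max(b * b - 4 * a * cc, 0.0)
    sq = np.sqrt(disc)
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if -1e-12 <= t <= 1 + 1e-12:
            return float(np.clip(t, 0.0, 1.0))
    return 0.5  # fallback; should not happen for a genuine crossing


def cap_plane_boundary(mesh: SurfaceMesh, plane: Plane3) -> SurfaceMesh:
    """Close boundary loops that lie in ``plane`` with triangle fans.

    Intended for re-closing a mesh after a half-space clip so mass properties
    can be computed.
    """
    e = np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    es = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(es, axis=0, return_inverse=True, return_counts=True)
    boundary_dir = {}
    for k, (a, b) in enumerate(e):
        key = inv[k]
        if counts[key] == 1:
            boundary_dir[(int(a), int(b))] = True
    if not boundary_dir:
        return mesh
    # chain boundary edges (directed, so loops inherit orientation)
    nxt = {}
    for a, b in boundary_dir:
        nxt[a] = b
    verts = [mesh.vertices]
    faces = [mesh.faces]
    offset = mesh.n_vertices
    visited = set()
    for a0 in list(nxt):
        if a0 in visited:
            continue
        loop = [a0]
        visited.add(a0)
        cur = nxt[a0]
        while cur != a0 and cur in nxt and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = nxt[cur]
        if len(loop) < 3:
            continue
        pts = mesh.vertices[loop]
        if np.abs(plane.signed_distance(pts)).max() > 1e-6:
            continue  # not the cut boundary
        centroid = pts.mean(axis=0)
        verts.append(centroid[None, :])
        li = np.array(loop)
        fan = np.stack([np.full(len(loop), offset), np.roll(li, -1), li], axis=1)
        faces.append(fan)
        offset += 1
    return SurfaceMesh(np.concatenate(verts), np.concatenate(faces), clean=False)


def intersect_line_mesh(mesh: SurfaceMesh, line) -> tuple[np.ndarray, np.ndarray]:
    """All intersection points of an infinite line with the mesh surface.

    Returns (points (K,3), line parameters (K,)), sorted by parameter.
    Vectorized Moller-Trumbore over all faces.
    """
    o = np.asarray(line.point, dtype=float)
    d = np.asarray(line.direction, dtype=float)
    tri = mesh.triangles()
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    s = o - tri[:, 0]
    u = np.einsum("ij,ij->i", s, p) * inv
    q = np.cross(s, e1)
    v = np.einsum("j,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    ts = np.sort(t[hit])
    # deduplicate hits on shared edges
    if len(ts):
        keep = np.concatenate([[True], np.diff(ts) > 1e-9])
        ts = ts[keep]
    return o + ts[:, None] * d, ts


def silhouette(mesh: SurfaceMesh, view_direction) -> list[PlanarContour]:
    """Outline of the orthographic projection of the mesh along a direction.

    Returns the outer boundary of each connected component of the projected
    shadow, as closed contours in the projection plane through the mesh
    centroid. Degenerate (edge-on) input raises.
    """
    w = unit(view_direction)
    plane = Plane3(mesh.vertices.mean(axis=0), w)
    u, v = plane.basis()
    q = mesh.vertices - plane.point
    xy = np.column_stack([q @ u, q @ v])
    tris = xy[mesh.faces]
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    areas2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    keep = areas2 > 1e-12
    if not keep.any():
        raise MeshError("silhouette: mesh is degenerate along the view direction")
    polys = shapely.polygons(tris[keep])
    merged = unary_union(polys)
    if merged.is_empty or merged.area < 1e-12:
        raise MeshError("silhouette: projection has no area")
    geoms = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    out = []
    for g in geoms:
        coords = np.asarray(g.exterior.coords)[:-1]
        pts = plane.point + np.outer(coords[:, 0], u) + np.outer(coords[:, 1], v)
        out.append(PlanarContour(points=pts, plane=plane, closed=True))
    out.sort(key=lambda c: -c.area)
    return out
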