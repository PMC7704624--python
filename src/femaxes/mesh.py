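"""Triangle surface mesh data model and mass properties.

The mesh is the universal geometric substrate of the pipeline: an indexed
triangle soup with counter-clockwise outward-facing triangles, coordinates in
millimetres. Cleaning (vertex merging, degenerate-face removal) happens once
at construction; downstream operations may assume a clean mesh.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MeshError
from .transforms import RigidTransform

MERGE_TOL = 1e-6  # mm; STL writers duplicate vertices per facet


@dataclass
class SurfaceMesh:
    """Indexed triangle mesh.

    Parameters
    ----------
    vertices : (N, 3) float array, millimetres.
    faces : (M, 3) int array of vertex indices, counter-clockwise outward.
    clean : merge duplicate vertices (1e-6 mm) and drop degenerate faces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    units: str = "mm"

    def __init__(self, vertices, faces, units: str = "mm", clean: bool = True):
        v = np.ascontiguousarray(np.asarray(vertices, dtype=float).reshape(-1, 3))
        f = np.ascontiguousarray(np.asarray(faces, dtype=np.int64).reshape(-1, 3))
        if len(v) == 0 or len(f) == 0:
            raise MeshError("empty mesh")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshError("face indices out of range")
        if clean:
            v, f = _clean(v, f)
            if len(f) == 0:
                raise MeshError("mesh has no non-degenerate faces")
        self.vertices = v
        self.faces = f
        self.units = units
        self._closed = None

    # -- basic properties ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(M, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        return n / lens[:, None]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edges_unique(self) -> np.ndarray:
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        if self._closed is None:
            e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                self.faces[:, [2, 0]]])
            e = np.sort(e, axis=1)
            _, counts = np.unique(e, axis=0, return_counts=True)
            self._closed = bool(np.all(counts == 2))
        return self._closed

    def bounds(self) -> np.ndarray:
        """(2, 3) [min; max] corner of the axis-aligned bounding box."""
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def extent_along(self, direction) -> float:
        d = np.asarray(direction, dtype=float)
        s = self.vertices @ d
        return float(s.max() - s.min())

    # -- derived meshes -----------------------------------------------------

    def transformed(self, T: RigidTransform) -> "SurfaceMesh":
        return SurfaceMesh(T.apply(self.vertices), self.faces, self.units, clean=False)

    def scaled(self, factor: float) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices * float(factor), self.faces, self.units, clean=False)

    def mirrored(self, axis: int = 1) -> "SurfaceMesh":
        """Reflect across the coordinate plane orthogonal to ``axis`` and flip
        face winding so triangles stay outward-facing."""
        v = self.vertices.copy()
        v[:, axis] = -v[:, axis]
        return SurfaceMesh(v, self.faces[:, ::-1], self.units, clean=False)

    def submesh(self, face_mask) -> "SurfaceMesh":
        f = self.faces[np.asarray(face_mask)]
        if len(f) == 0:
            raise MeshError("submesh selection is empty")
        used, inv = np.unique(f, return_inverse=True)
        return SurfaceMesh(self.vertices[used], inv.reshape(-1, 3), self.units, clean=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.units, clean=False)


def _clean(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices within MERGE_TOL, drop degenerate faces, drop unused vertices."""
    key = np.round(v / MERGE_TOL).astype(np.int64)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    v = v[first]
    f = inv[f]
    # drop faces with repeated indices
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 2] != f[:, 0])
    f = f[ok]
    if len(f):
        t = v[f]
        areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        f = f[areas > 1e-12]
    if len(f):
        used, inv2 = np.unique(f, return_inverse=True)
        v = v[used]
        f = inv2.reshape(-1, 3)
    return np.ascontiguousarray(v), np.ascontiguousarray(f)


# canonical second moment of the unit tetrahedron (0, e1, e2, e3):
# integral of x_i x_j over its volume
_C_TET = (np.full((3, 3), 1.0 / 120.0) + np.eye(3) * (1.0 / 120.0))


def signed_volume(mesh: SurfaceMesh, origin=(0.0, 0.0, 0.0)) -> float:
    """Signed volume by summing signed tetrahedra from ``origin``.

    Exact for closed meshes; for an open mesh whose boundary loops lie in a
    plane containing ``origin``, the missing cap contributes zero, so this
    still returns the enclosed volume.
    """
    o = np.asarray(origin, dtype=float)
    t = mesh.triangles() - o
    return float(np.einsum('ij,ij->i', t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def mass_properties(mesh: SurfaceMesh) -> tuple[float, np.ndarray, np.ndarray]:
    """Volume (mm^3), center of mass and inertia tensor about the COM.

    Divergence-theorem accumulation of signed tetrahedra, unit density.
    Requires a closed mesh.
    """
    if not mesh.is_closed:
        raise MeshError("mass properties require a closed mesh")
    t = mesh.triangles()
    d6 = np.einsum('ij,ij->i', t[:, 0], np.cross(t[:, 1], t[:, 2]))  # 6 * signed vol
    volume = d6.sum() / 6.0
    if volume <= 0:
        raise MeshError("non-positive volume; faces may be inward-oriented")
    com = (d6[:, None] * t.sum(axis=1)).sum(axis=0) / (24.0 * volume)
    # second moment about the origin: sum over tetra of det(A) * A @ C @ A.T
    # with A = [v0 v1 v2] columns
    A = np.transpose(t, (0, 2, 1))  # (M, 3, 3) columns are vertices
    S = np.einsum('m,mij,jk,mlk->il', d6, A, _C_TET, A)
    S_com = S - volume * np.outer(com, com)
    inertia = np.trace(S_com) * np.eye(3) - S_com
    inertia = 0.5 * (inertia + inertia.T)
    return float(volume), com, inertia


def merge_meshes(meshes) -> SurfaceMesh:
    """Concatenate meshes into a single (possibly disjoint) mesh."""
    vs, fs, off = [], [], 0
    for m in meshes:
        vs.append(m.vertices)
        fs.append(m.faces + off)
        off += m.n_vertices
    return SurfaceMesh(np.concatenate(vs), np.concatenate(fs), clean=False)
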