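"""Canonical test solids (box, sphere, cylinder, torus)."""
from __future__ import annotations

import numpy as np

from .mesh import SurfaceMesh


def box(extents=(1.0, 1.0, 1.0), center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Axis-aligned box with the canonical 12-triangle tessellation."""
    e = np.asarray(extents, dtype=float) / 2.0
    c = np.asarray(center, dtype=float)
    corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
                       dtype=float)
    v = corners * e + c
    # outward CCW faces for corner ordering (x, y, z) in {-,+}^3 (binary index)
    f = np.array([
        [0, 1, 3], [0, 3, 2],  # -x
        [4, 6, 7], [4, 7, 5],  # +x
        [0, 4, 5], [0, 5, 1],  # -y
        [2, 3, 7], [2, 7, 6],  # +y
        [0, 2, 6], [0, 6, 4],  # -z
        [1, 5, 7], [1, 7, 3],  # +z
    ])
    return SurfaceMesh(v, f, clean=False)


def icosphere(radius: float = 1.0, center=(0.0, 0.0, 0.0), subdivisions: int = 3) -> SurfaceMesh:
    """Subdivided icosahedron with vertices exactly on the sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v[0])
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
        v /= np.linalg.norm(v, axis=1)[:, None]
    return SurfaceMesh(v * radius + np.asarray(center, dtype=float), f, clean=False)


def _subdivide(v: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges_sorted, axis=0, return_inverse=True)
    mids = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    mid_idx = inv.reshape(3, -1).T + len(v)  # (M, 3): midpoints of edges 01, 12, 20
    a, b, c = f[:, 0], f[:, 1], f[:, 2]
    ab, bc, ca = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    newf = np.concatenate([
        np.stack([a, ab, ca], axis=1),
        np.stack([b, bc, ab], axis=1),
        np.stack([c, ca, bc], axis=1),
        np.stack([ab, bc, ca], axis=1),
    ])
    return np.concatenate([v, mids]), newf


def cylinder(radius: float = 1.0, height: float = 2.0, sections: int = 64,
             center=(0.0, 0.0, 0.0), capped: bool = True) -> SurfaceMesh:
    """Cylinder along z with ``sections`` facets around the circumference."""
    th = np.linspace(0.0, 2.0 * np.pi, sections, endpoint=False)
    ring = np.stack([radius * np.cos(th), radius * np.sin(th)], axis=1)
    bot = np.column_stack([ring, np.full(sections, -height / 2.0)])
    top = np.column_stack([ring, np.full(sections, height / 2.0)])
    v = np.concatenate([bot, top])
    i = np.arange(sections)
    j = (i + 1) % sections
    side = np.concatenate([
        np.stack([i, j, sections + j], axis=1),
        np.stack([i, sections + j, sections + i], axis=1),
    ])
    faces = [side]
    if capped:
        cb = len(v)
        ct = cb + 1
        v = np.concatenate([v, [[0, 0, -height / 2.0], [0, 0, height / 2.0]]])
        faces.append(np.stack([np.full(sections, cb), j, i], axis=1))
        faces.append(np.stack([np.full(sections, ct), sections + i, sections + j], axis=1))
    return SurfaceMesh(v + np.asarray(center, dtype=float), np.concatenate(faces), clean=False)


def torus(major_radius: float = 2.0, minor_radius: float = 0.5,
          major_sections: int = 48, minor_sections: int = 24,
          center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Torus around the z axis."""
    u = np.linspace(0, 2 * np.pi, major_sections, endpoint=False)
    w = np.linspace(0, 2 * np.pi, minor_sections, endpoint=False)
    uu, ww = np.meshgrid(u, w, indexing="ij")
    r = major_radius + minor_radius * np.cos(ww)
    v = np.stack([r * np.cos(uu), r * np.sin(uu), minor_radius * np.sin(ww)], axis=-1)
    v = v.reshape(-1, 3)
    idx = np.arange(major_sections * minor_sections).reshape(major_sections, minor_sections)
    i0 = idx
    i1 = np.roll(idx, -1, axis=0)
    j1 = np.roll(idx, -1, axis=1)
    j01 = np.roll(i1, -1, axis=1)
    f = np.concatenate([
        np.stack([i0.ravel(), i1.ravel(), j01.ravel()], axis=1),
        np.stack([i0.ravel(), j01.ravel(), j1.ravel()], axis=1),
    ])
    return SurfaceMesh(v + np.asarray(center, dtype=float), f, clean=False)
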