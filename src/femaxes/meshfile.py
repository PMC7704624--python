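"""Mesh file I/O: STL (ASCII + binary), PLY (ASCII + binary little-endian), OBJ.

Units are fixed to millimetres by input contract; file headers are not
inspected for units (STL has none).
"""
from __future__ import annotations

import os
import struct

import numpy as np

from .errors import MeshIOError
from .mesh import SurfaceMesh

_FORMATS = ("stl", "ply", "obj")


def _format_from_path(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshIOError(f"unsupported mesh format {fmt!r} (expected one of {_FORMATS})")
    return fmt


def load_mesh(path: str, fmt: str | None = None) -> SurfaceMesh:
    """Load and clean a triangle mesh from STL/PLY/OBJ.

    Duplicate vertices are merged (1e-6 mm) and degenerate faces dropped;
    the closedness flag is available as ``mesh.is_closed``.
    """
    fmt = _format_from_path(path, fmt)
    try:
        with open(path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise MeshIOError(f"cannot read {path}: {exc}") from exc
    if fmt == "stl":
        v, f = _read_stl(data)
    elif fmt == "ply":
        v, f = _read_ply(data)
    else:
        v, f = _read_obj(data)
    if len(v) == 0 or len(f) == 0:
        raise MeshIOError(f"{path}: mesh is empty")
    return SurfaceMesh(v, f, clean=True)


def save_mesh(mesh: SurfaceMesh, path: str, fmt: str | None = None,
              binary: bool = False) -> None:
    """Write a mesh. ``binary`` selects binary STL / binary_little_endian PLY."""
    fmt = _format_from_path(path, fmt)
    if fmt == "stl":
        data = _write_stl_binary(mesh) if binary else _write_stl_ascii(mesh)
    elif fmt == "ply":
        data = _write_ply(mesh, binary=binary)
    else:
        data = _write_obj(mesh)
    with open(path, "wb") as fh:
        fh.write(data)


# ---------------------------------------------------------------------- STL

def _read_stl(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    if _looks_binary_stl(data):
        return _read_stl_binary(data)
    return _read_stl_ascii(data)


def _looks_binary_stl(data: bytes) -> bool:
    if len(data) < 84:
        return False
    n = struct.unpack("<I", data[80:84])[0]
    if len(data) == 84 + 50 * n:
        return True
    return not data.lstrip()[:5].lower().startswith(b"solid")


def _read_stl_binary(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    n = struct.unpack("<I", data[80:84])[0]
    if len(data) < 84 + 50 * n:
        raise MeshIOError("truncated binary STL")
    rec = np.frombuffer(data, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(float)
    v = tri.reshape(-1, 3)
    f = np.arange(3 * n).reshape(-1, 3)
    return v, f


def _read_stl_ascii(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    verts = []
    try:
        text = data.decode("ascii", errors="replace")
    except Exception as exc:  # pragma: no cover
        raise MeshIOError(f"cannot decode ASCII STL: {exc}") from exc
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise MeshIOError(f"malformed STL vertex line: {line!r}")
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if len(verts) % 3 != 0:
        raise MeshIOError("ASCII STL vertex count is not a multiple of 3")
    v = np.asarray(verts, dtype=float)
    f = np.arange(len(v)).reshape(-1, 3)
    return v, f


def _write_stl_ascii(mesh: SurfaceMesh) -> bytes:
    tri = mesh.triangles()
    nrm = mesh.face_normals()
    out = ["solid femaxes"]
    for t, n in zip(tri, nrm):
        out.append(f" facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
        out.append("  outer loop")
        for p in t:
            out.append(f"   vertex {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
        out.append("  endloop")
        out.append(" endfacet")
    out.append("endsolid femaxes\n")
    return "\n".join(out).encode("ascii")


def _write_stl_binary(mesh: SurfaceMesh) -> bytes:
    tri = mesh.triangles().astype("<f4")
    nrm = mesh.face_normals().astype("<f4")
    n = len(tri)
    rec = np.zeros(n, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec["n"] = nrm
    rec["v"] = tri
    header = b"femaxes binary STL".ljust(80, b" ")
    return header + struct.pack("<I", n) + rec.tobytes()


# ---------------------------------------------------------------------- PLY

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise MeshIOError("not a PLY file")
    end = data.find(b"\n", end) + 1
    header = data[:end].decode("ascii", errors="replace")
    body = data[end:]

    fmt = None
    elements = []  # (name, count, [(prop_kind, dtype(s), name)])
    for line in header.splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise MeshIOError("PLY property before element")
            if parts[1] == "list":
                elements[-1][2].append(("list", (_PLY_TYPES[parts[2]], _PLY_TYPES[parts[3]]), parts[4]))
            else:
                elements[-1][2].append(("scalar", _PLY_TYPES[parts[1]], parts[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshIOError(f"unsupported PLY format {fmt!r}")
    if fmt == "ascii":
        return _read_ply_ascii(body, elements)
    return _read_ply_binary(body, elements)


def _read_ply_ascii(body: bytes, elements) -> tuple[np.ndarray, np.ndarray]:
    tokens = body.split()
    pos = 0
    verts, faces = None, []
    for name, count, props in elements:
        if name == "vertex":
            ncols = len(props)
            arr = np.array(tokens[pos:pos + count * ncols], dtype=float).reshape(count, ncols)
            pos += count * ncols
            names = [p[2] for p in props]
            verts = arr[:, [names.index("x"), names.index("y"), names.index("z")]]
        elif name == "face":
            for _ in range(count):
                n = int(tokens[pos]); pos += 1
                idx = [int(t) for t in tokens[pos:pos + n]]; pos += n
                for k in range(1, n - 1):
                    faces.append([idx[0], idx[k], idx[k + 1]])
        else:  # skip unknown element (scalar properties only)
            pos += count * len(props)
    if verts is None:
        raise MeshIOError("PLY file has no vertex element")
    return verts, np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _read_ply_binary(body: bytes, elements) -> tuple[np.ndarray, np.ndarray]:
    pos = 0
    verts, faces = None, []
    for name, count, props in elements:
        if all(p[0] == "scalar" for p in props):
            dt = np.dtype([(p[2], "<" + p[1]) for p in props])
            arr = np.frombuffer(body, dtype=dt, count=count, offset=pos)
            pos += dt.itemsize * count
            if name == "vertex":
                verts = np.stack([arr["x"], arr["y"], arr["z"]], axis=1).astype(float)
        else:
            for _ in range(count):
                for kind, dtypes, _pname in props:
                    if kind == "scalar":
                        pos += np.dtype(dtypes).itemsize
                    else:
                        cdt = np.dtype("<" + dtypes[0])
                        n = int(np.frombuffer(body, dtype=cdt, count=1, offset=pos)[0])
                        pos += cdt.itemsize
                        idt = np.dtype("<" + dtypes[1])
                        idx = np.frombuffer(body, dtype=idt, count=n, offset=pos)
                        pos += idt.itemsize * n
                        if name == "face":
                            for k in range(1, n - 1):
                                faces.append([idx[0], idx[k], idx[k + 1]])
    if verts is None:
        raise MeshIOError("PLY file has no vertex element")
    return verts, np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _write_ply(mesh: SurfaceMesh, binary: bool) -> bytes:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        "comment femaxes\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    ).encode("ascii")
    if binary:
        vbuf = mesh.vertices.astype("<f8").tobytes()
        frec = np.zeros(mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", 3)])
        frec["n"] = 3
        frec["idx"] = mesh.faces
        return header + vbuf + frec.tobytes()
    lines = [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    return header + ("\n".join(lines) + "\n").encode("ascii")


# ---------------------------------------------------------------------- OBJ

def _read_obj(data: bytes) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for raw in data.decode("utf-8", errors="replace").splitlines():
        line = raw.strip()
        if line.startswith("v "):
            parts = line.split()
            verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif line.startswith("f "):
            idx = []
            for tok in line.split()[1:]:
                i = int(tok.split("/")[0])
                idx.append(i - 1 if i > 0 else len(verts) + i)
            for k in range(1, len(idx) - 1):
                faces.append([idx[0], idx[k], idx[k + 1]])
    return np.asarray(verts, dtype=float).reshape(-1, 3), \
        np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _write_obj(mesh: SurfaceMesh) -> bytes:
    lines = [f"v {x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
    return ("\n".join(lines) + "\n").encode("ascii")
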