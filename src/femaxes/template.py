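"""Atlas template: a mesh annotated with named landmark vertices and named
vertex regions, pre-aligned to the temporary femoral coordinate system (TFCS:
x distal-/proximal+, y medial-/lateral+, z posterior-/anterior+).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, MeshError
from .mesh import SurfaceMesh
from .meshfile import load_mesh, save_mesh
from .synthetic import FemurSpec, GroundTruth, generate_femur
from .transforms import unit

TEMPLATE_SCHEMA_VERSION = 1

REQUIRED_REGIONS = ("head", "neck", "medial_condyle", "lateral_condyle")
REQUIRED_LANDMARKS = ("MEC", "LEC", "MPC", "LPC", "PTC", "ICN", "SGT", "LT")


@dataclass
class AtlasTemplate:
    """TFCS-aligned template mesh with landmark vertices and vertex regions."""

    mesh: SurfaceMesh
    landmarks: dict          # name -> vertex index
    regions: dict            # name -> int array of vertex indices
    rig: dict                # neck_base, neck_dir, shaft_dir (TFCS coords) + parameters
    side: str = "right"
    ground_truth: GroundTruth | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.mesh.n_vertices
        for name in REQUIRED_LANDMARKS:
            if name not in self.landmarks:
                raise MeshError(f"template is missing landmark {name!r}")
        for name in REQUIRED_REGIONS:
            if name not in self.regions:
                raise MeshError(f"template is missing region {name!r}")
        for name, idx in self.landmarks.items():
            if not 0 <= int(idx) < n:
                raise MeshError(f"landmark {name!r} index out of range")
        self.regions = {k: np.asarray(v, dtype=np.int64) for k, v in self.regions.items()}
        for name, idx in self.regions.items():
            if len(idx) == 0:
                raise MeshError(f"region {name!r} is empty")
            if idx.min() < 0 or idx.max() >= n:
                raise MeshError(f"region {name!r} has indices out of range")

    def landmark_point(self, name: str) -> np.ndarray:
        return self.mesh.vertices[self.landmarks[name]]

    def region_points(self, name: str) -> np.ndarray:
        return self.mesh.vertices[self.regions[name]]

    def save(self, mesh_path: str, sidecar_path: str | None = None) -> None:
        save_mesh(self.mesh, mesh_path, fmt="ply")
        if sidecar_path is None:
            sidecar_path = mesh_path + ".json"
        doc = {
            "schema_version": TEMPLATE_SCHEMA_VERSION,
            "side": self.side,
            "landmarks": {k: int(v) for k, v in self.landmarks.items()},
            "regions": {k: [int(i) for i in v] for k, v in self.regions.items()},
            "rig": {k: (list(v) if isinstance(v, np.ndarray) else v)
                    for k, v in self.rig.items()},
        }
        with open(sidecar_path, "w") as fh:
            json.dump(doc, fh)

    @staticmethod
    def load(mesh_path: str, sidecar_path: str | None = None) -> "AtlasTemplate":
        if sidecar_path is None:
            sidecar_path = mesh_path + ".json"
        mesh = load_mesh(mesh_path)
        with open(sidecar_path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != TEMPLATE_SCHEMA_VERSION:
            raise MeshError("unsupported template schema version")
        rig = {k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
               for k, v in doc["rig"].items()}
        return AtlasTemplate(mesh=mesh, landmarks=doc["landmarks"],
                             regions=doc["regions"], rig=rig,
                             side=doc.get("side", "right"))


def generate_template(spec: FemurSpec) -> AtlasTemplate:
    """Generate a synthetic femur and annotate it as an atlas template.

    The template is rigidly moved to its TFCS (principal axes of inertia,
    center of mass at the origin); the eigenvector sign ambiguity is resolved
    with the generator's ground truth so that x points proximally and z
    anteriorly.
    """
    from .registration import align_to_tfcs  # deferred: avoid import cycle

    mesh, gt = generate_femur(spec)
    _, T = align_to_tfcs(mesh)
    # fix eigenvector signs from ground truth: x proximal, z anterior
    R = T.rotation
    ex, ez = R[0], R[2]
    fhc_dir = gt.landmarks["FHC"] - mesh.vertices.mean(axis=0)
    if np.dot(ex, fhc_dir) < 0:
        ex = -ex
    if np.dot(ez, gt.planes["TTP"].normal) > 0:  # TTP normal points posterior
        ez = -ez
    ey = np.cross(ez, ex)
    from .transforms import RigidTransform
    Rfix = np.stack([ex, unit(ey), ez])
    T = RigidTransform(Rfix, -Rfix @ T.inverse().translation)
    mesh = mesh.transformed(T)
    gt = gt.transformed(T)

    nl = spec.neck_length
    nb = gt.neck_base
    ndir = gt.axes["neck"].direction
    v = mesh.vertices

    regions: dict[str, np.ndarray] = {}
    fhc = gt.landmarks["FHC"]
    rel = v - fhc
    dist_fhc = np.linalg.norm(rel, axis=1)
    toward_neck = unit(nb - fhc)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arccos(np.clip(
            (rel / np.maximum(dist_fhc, 1e-12)[:, None]) @ toward_neck, -1, 1)))
    regions["head"] = np.where((dist_fhc <= 1.05 * spec.head_radius) & (ang >= 50.0))[0]

    t_axial = (v - nb) @ ndir
    radial = np.linalg.norm(v - nb - np.outer(t_axial, ndir), axis=1)
    neck_r = 0.5 * spec.head_radius
    regions["neck"] = np.where((t_axial >= 0.35 * nl) & (t_axial <= 0.65 * nl)
                               & (radial <= neck_r + 3.0))[0]

    for name, key in (("medial_condyle", "medial"), ("lateral_condyle", "lateral")):
        con = gt.condyles[key]
        q = (v - con["center"]) @ np.asarray(con["axes"]).T / np.asarray(con["radii"])
        scaled = np.linalg.norm(q, axis=1)
        margin = 1.5 / float(np.min(con["radii"]))
        regions[name] = np.where(scaled <= 1.0 + margin)[0]

    for name in REQUIRED_REGIONS:
        if len(regions[name]) == 0:
            raise GenerationError(f"template region {name!r} empty at this tessellation")

    landmarks = {}
    for name in REQUIRED_LANDMARKS:
        landmarks[name] = int(np.argmin(np.linalg.norm(v - gt.landmarks[name], axis=1)))

    rig = {
        "neck_base": nb.copy(),
        "neck_dir": ndir.copy(),
        "shaft_dir": gt.axes["shaft"].direction.copy(),
        "ccd_angle": spec.ccd_angle,
        "version_angle": spec.version_angle,
        "neck_length": spec.neck_length,
    }
    return AtlasTemplate(mesh=mesh, landmarks=landmarks, regions=regions, rig=rig,
                         side=spec.side, ground_truth=gt)


_DEFAULT_TEMPLATE_CACHE: dict[tuple, AtlasTemplate] = {}


def default_template(side: str = "right") -> AtlasTemplate:
    """The packaged template: generated deterministically, cached per side.

    Registration canonicalizes left subjects by mirroring, so the packaged
    template is right-sided; ``side`` is exposed for testing symmetry.
    """
    key = (side,)
    if key not in _DEFAULT_TEMPLATE_CACHE:
        from .synthetic import default_spec
        spec = default_spec(side=side, voxel_pitch=4.0, subdivisions=0)
        _DEFAULT_TEMPLATE_CACHE[key] = generate_template(spec)
    return _DEFAULT_TEMPLATE_CACHE[key]
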