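"""Stage 1: atlas-based registration.

TFCS alignment by principal axes of inertia, grid pre-registration,
parametric template deformation (two-bone linear blend skinning over the
neck-shaft junction), locally affine nonrigid ICP, and transfer of template
landmarks/regions to the subject surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .errors import MeshError, StageError
from .mesh import SurfaceMesh, mass_properties
from .template import AtlasTemplate
from .transforms import RigidTransform, rotation_about_axis, rotation_x, rotation_y, unit


# ----------------------------------------------------------------- TFCS

def align_to_tfcs(mesh: SurfaceMesh) -> tuple[SurfaceMesh, RigidTransform]:
    """Move a closed mesh to its principal axes of inertia.

    Output: center of mass at the origin; x = smallest-inertia eigenvector
    (the long axis), z = largest. Eigenvector signs are chosen
    deterministically but carry no anatomical meaning; the anatomical
    orientation of Table-2 type (x proximal, y lateral, z anterior) is only
    attempted and is resolved downstream by pre-registration.
    """
    _, com, inertia = mass_properties(mesh)
    evals, evecs = np.linalg.eigh(inertia)  # ascending
    gaps = np.diff(evals) / max(evals[-1], 1e-300)
    if np.any(gaps < 1e-9):
        raise MeshError("near-degenerate inertia tensor; TFCS axes are ambiguous")
    rows = evecs.T  # x = smallest inertia, y = middle, z = largest
    for i in range(3):
        j = np.argmax(np.abs(rows[i]))
        if rows[i][j] < 0:
            rows[i] = -rows[i]
    if np.linalg.det(rows) < 0:
        rows[1] = -rows[1]
    T = RigidTransform(rows, -rows @ com)
    return mesh.transformed(T), T


def scale_to_template(subject: SurfaceMesh, template: AtlasTemplate) -> tuple[SurfaceMesh, float]:
    """Isotropic scale so the subject's x-extent equals the template's."""
    ext_s = subject.extent_along([1.0, 0.0, 0.0])
    ext_t = template.mesh.extent_along([1.0, 0.0, 0.0])
    if ext_s <= 0:
        raise MeshError("subject has zero x-extent")
    s = ext_t / ext_s
    return subject.scaled(s), float(s)


# --------------------------------------------------------- pre-registration

def rough_preregister(subject: SurfaceMesh, template: AtlasTemplate,
                      coarse_step_deg: float = 10.0,
                      fine_step_deg: float = 5.0,
                      distal_fraction: float = 0.4,
                      sample_limit: int = 4000) -> RigidTransform:
    """Grid search for the rotation that best aligns the subject to the
    template: {0..350 step 10 deg about x} x {0, 180 deg about y}, scored by
    the sum of template-to-subject nearest-neighbor distances, then a 5-deg
    x-rotation refinement scored on the distal part only.

    Returns the rotation to apply to the subject. Both meshes must be
    TFCS-aligned and scaled.
    """
    tp = _sample(template.mesh.vertices, sample_limit)
    tree = cKDTree(subject.vertices)

    def score(R, pts):
        # template -> rotated subject == inverse-rotated template -> subject
        d, _ = tree.query(pts @ R)  # pts @ R == R.T applied to rows
        return float(d.sum())

    best = (np.inf, None)
    for flip in (0.0, 180.0):
        Ry = rotation_y(flip)
        for ang in np.arange(0.0, 360.0, coarse_step_deg):
            R = rotation_x(ang) @ Ry
            s = score(R, tp)
            if s < best[0]:
                best = (s, R)
    R0 = best[1]

    # distal refinement about x
    x = template.mesh.vertices[:, 0]
    cut = x.min() + distal_fraction * (x.max() - x.min())
    tp_dist = _sample(template.mesh.vertices[x <= cut], sample_limit)
    best_fine = (np.inf, R0)
    for ang in np.arange(-coarse_step_deg, coarse_step_deg + 1e-9, fine_step_deg):
        R = rotation_x(ang) @ R0
        s = score(R, tp_dist)
        if s < best_fine[0]:
            best_fine = (s, R)
    return RigidTransform(best_fine[1], np.zeros(3))


def _sample(points: np.ndarray, limit: int) -> np.ndarray:
    if len(points) <= limit:
        return points
    idx = np.linspace(0, len(points) - 1, limit).astype(int)
    return points[idx]


# ------------------------------------------------- parametric deformation

def _lbs_weights(template: AtlasTemplate, blend_mm: float = 25.0) -> np.ndarray:
    """Smoothstep weight of the neck-head bone per template vertex.

    1 on the head/neck side of the neck-shaft junction, 0 on the shaft,
    with a smooth ramp across ``blend_mm``.
    """
    nb = np.asarray(template.rig["neck_base"], dtype=float)
    ndir = unit(template.rig["neck_dir"])
    t = (template.mesh.vertices - nb) @ ndir
    s = np.clip((t + blend_mm / 2.0) / blend_mm, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def apply_lbs(template: AtlasTemplate, d_version: float, d_ccd: float,
              d_neck: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Deformed vertex positions for parameter offsets (degrees, degrees, mm).

    Two-bone rig: the shaft bone is fixed; the neck-head bone rotates about
    the neck base (version about the shaft axis, CCD about the axis normal
    to the neck-shaft plane) and stretches along the neck axis.
    """
    if weights is None:
        weights = _lbs_weights(template)
    nb = np.asarray(template.rig["neck_base"], dtype=float)
    ndir = unit(template.rig["neck_dir"])
    R = _neck_bone_rotation(template, d_version, d_ccd)
    v = template.mesh.vertices
    moved = (v - nb) @ R.T + nb + d_neck * (R @ ndir)
    return v + weights[:, None] * (moved - v)


def _neck_bone_rotation(template: AtlasTemplate, d_version: float, d_ccd: float) -> np.ndarray:
    """Rotation of the neck-head bone about the neck base.

    Positive ``d_version`` increases anteversion; positive ``d_ccd`` opens the
    neck-shaft angle (moves the neck direction toward the proximal shaft
    direction).
    """
    ndir = unit(template.rig["neck_dir"])
    sdir = unit(template.rig["shaft_dir"])
    ccd_axis = np.cross(ndir, sdir)
    if np.linalg.norm(ccd_axis) < 1e-12:  # pragma: no cover - degenerate rig
        ccd_axis = np.array([0.0, 0.0, 1.0])
    # rotating about cross(ndir, sdir) by +angle moves ndir toward sdir,
    # which increases the CCD angle (CCD = 180 deg - angle(ndir, sdir)).
    Rv = rotation_about_axis(sdir, -d_version)
    Rc = rotation_about_axis(unit(ccd_axis), d_ccd)
    return Rv @ Rc


def deformed_rig(template: AtlasTemplate, d_version: float, d_ccd: float,
                 d_neck: float) -> dict:
    """Rig (neck axis etc.) after the same deformation as :func:`apply_lbs`."""
    nb = np.asarray(template.rig["neck_base"], dtype=float)
    ndir = unit(template.rig["neck_dir"])
    R = _neck_bone_rotation(template, d_version, d_ccd)
    rig = dict(template.rig)
    rig["neck_dir"] = R @ ndir
    rig["neck_base"] = nb
    rig["ccd_angle"] = template.rig["ccd_angle"] + d_ccd
    rig["version_angle"] = template.rig["version_angle"] + d_version
    rig["neck_length"] = template.rig["neck_length"] + d_neck
    return rig


def deform_template(template: AtlasTemplate, subject: SurfaceMesh,
                    version_range: float = 20.0, ccd_range: float = 15.0,
                    neck_frac_range: float = 0.10, grid_step_deg: float = 5.0,
                    proximal_fraction: float = 0.35) -> tuple[AtlasTemplate, dict]:
    """Fit (version, CCD, neck length) offsets of the template to the subject
    by coarse grid search then local refinement of the proximal-part
    nearest-neighbor distance. Returns the deformed template and diagnostics.
    """
    weights = _lbs_weights(template)
    # score only the part the rig actually moves (head + neck side), so the
    # cost is sensitive to the parameters rather than dominated by the shaft
    prox_idx = np.where(weights > 0.2)[0]
    if len(prox_idx) < 50:  # pragma: no cover - degenerate rig
        x = template.mesh.vertices[:, 0]
        cut = x.max() - proximal_fraction * (x.max() - x.min())
        prox_idx = np.where(x >= cut)[0]
    tree = cKDTree(subject.vertices)
    nl = float(template.rig["neck_length"])

    def cost(params):
        dv, dc, dn = params
        dv = float(np.clip(dv, -version_range, version_range))
        dc = float(np.clip(dc, -ccd_range, ccd_range))
        dn = float(np.clip(dn, -neck_frac_range * nl, neck_frac_range * nl))
        pts = apply_lbs(template, dv, dc, dn, weights)[prox_idx]
        d, _ = tree.query(pts)
        return float(np.mean(d))

    best = (np.inf, (0.0, 0.0, 0.0))
    for dv in np.arange(-version_range, version_range + 1e-9, grid_step_deg):
        for dc in np.arange(-ccd_range, ccd_range + 1e-9, grid_step_deg):
            for dn in np.linspace(-neck_frac_range * nl, neck_frac_range * nl, 5):
                c = cost((dv, dc, dn))
                if c < best[0]:
                    best = (c, (dv, dc, dn))
    res = minimize(cost, best[1], method="Nelder-Mead",
                   options={"xatol": 0.05, "fatol": 1e-5, "maxfev": 250})
    dv, dc, dn = res.x
    clamped = (abs(dv) > version_range or abs(dc) > ccd_range
               or abs(dn) > neck_frac_range * nl)
    dv = float(np.clip(dv, -version_range, version_range))
    dc = float(np.clip(dc, -ccd_range, ccd_range))
    dn = float(np.clip(dn, -neck_frac_range * nl, neck_frac_range * nl))
    new_mesh = SurfaceMesh(apply_lbs(template, dv, dc, dn, weights),
                           template.mesh.faces, clean=False)
    out = AtlasTemplate(mesh=new_mesh, landmarks=dict(template.landmarks),
                        regions=dict(template.regions),
                        rig=deformed_rig(template, dv, dc, dn),
                        side=template.side, ground_truth=template.ground_truth)
    diag = {"d_version": dv, "d_ccd": dc, "d_neck": dn,
            "cost": float(res.fun), "clamped": bool(clamped)}
    return out, diag


# ------------------------------------------------------------ nonrigid ICP

def nonrigid_icp(template: AtlasTemplate, subject: SurfaceMesh,
                 stiffness_steps: int = 8, stiffness_start: float = 50.0,
                 stiffness_factor: float = 0.55, inner_iterations: int = 1,
                 gamma: float = 1.0,
                 converged_residual: float = 1.0) -> tuple[SurfaceMesh, dict]:
    """Locally affine nonrigid ICP of the template onto the subject.

    Per-vertex 3x4 affine transforms minimize nearest-neighbor distance to
    the subject plus an edge-wise stiffness regularizer, with the stiffness
    decreasing geometrically over the outer steps. Output vertex ``i``
    corresponds to template vertex ``i``.
    """
    V = template.mesh.n_vertices
    verts = template.mesh.vertices
    edges = template.mesh.edges_unique()
    E = len(edges)
    tree = cKDTree(subject.vertices)

    G = sp.diags([1.0, 1.0, 1.0, gamma])
    rows = np.repeat(np.arange(E), 2)
    cols = edges.ravel()
    vals = np.tile([-1.0, 1.0], E)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(E, V))
    MG = sp.kron(M, G).tocsr()            # (4E, 4V)
    D = sp.lil_matrix((V, 4 * V))
    for j in range(3):
        D[np.arange(V), np.arange(V) * 4 + j] = verts[:, j]
    D[np.arange(V), np.arange(V) * 4 + 3] = 1.0
    D = D.tocsr()
    DtD = (D.T @ D).tocsc()
    StS = (MG.T @ MG).tocsc()

    X = np.zeros((4 * V, 3))
    X[0::4] = np.eye(3)[0]
    X[1::4] = np.eye(3)[1]
    X[2::4] = np.eye(3)[2]

    current = verts.copy()
    residuals = []
    alpha = stiffness_start
    for _ in range(stiffness_steps):
        lhs = (alpha ** 2) * StS + DtD
        solver = splu(lhs.tocsc())
        for _ in range(inner_iterations):
            d, idx = tree.query(current)
            U = subject.vertices[idx]
            rhs = D.T @ U
            X = solver.solve(rhs)
            current = D @ X
        d, _ = tree.query(current)
        residuals.append(float(np.mean(d)))
        alpha *= stiffness_factor
    diag = {"residuals": residuals, "final_residual": residuals[-1],
            "converged": residuals[-1] < converged_residual}
    deformed = SurfaceMesh(current, template.mesh.faces, clean=False)
    return deformed, diag


# ------------------------------------------------------------------ mapping

@dataclass
class MappedAnatomy:
    """Template landmarks/regions transferred onto the subject surface."""

    landmarks: dict                    # name -> (3,) point on subject
    regions: dict                      # name -> (K, 3) points on subject
    region_indices: dict = field(default_factory=dict)  # name -> subject vertex ids
    landmark_indices: dict = field(default_factory=dict)


def map_anatomy(deformed_template: AtlasTemplate | SurfaceMesh,
                template: AtlasTemplate, subject: SurfaceMesh) -> MappedAnatomy:
    """Map template landmarks and regions to their nearest subject vertices.

    ``deformed_template`` provides the vertex positions (in subject space);
    ``template`` provides the annotation indices.
    """
    mesh = deformed_template.mesh if isinstance(deformed_template, AtlasTemplate) \
        else deformed_template
    if mesh.n_vertices != template.mesh.n_vertices:
        raise StageError("mapping", "deformed template does not match template topology")
    tree = cKDTree(subject.vertices)
    landmarks, lm_idx = {}, {}
    for name, vi in template.landmarks.items():
        _, j = tree.query(mesh.vertices[int(vi)])
        landmarks[name] = subject.vertices[j].copy()
        lm_idx[name] = int(j)
    regions, reg_idx = {}, {}
    for name, ids in template.regions.items():
        _, j = tree.query(mesh.vertices[np.asarray(ids, dtype=int)])
        j = np.unique(j)
        if len(j) == 0:
            raise StageError("mapping", f"mapped region {name!r} is empty")
        regions[name] = subject.vertices[j].copy()
        reg_idx[name] = j
    return MappedAnatomy(landmarks=landmarks, regions=regions,
                         region_indices=reg_idx, landmark_indices=lm_idx)
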