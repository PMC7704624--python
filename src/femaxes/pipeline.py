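"""Full detection pipeline: registration stage, refinement stage, frames.

The subject mesh may be in any spatial pose (the pipeline is alignment
robust). Left femora are mirrored to the canonical right-side pose for
processing and the results are mirrored back, so all outputs are in the
original world coordinates of the input mesh.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import DetectConfig
from .errors import StageError
from .frames import (BoneFrame, build_bergmann2016, build_tabletop, build_wu2002)
from .mesh import SurfaceMesh
from .refinement import (AnatomyResult, compute_usp, detect_epicondyles,
                         detect_icn, detect_shaft_axis, detect_ttp,
                         passthrough_landmarks, refine_fhc, refine_neck_axis)
from .registration import (align_to_tfcs, deform_template, map_anatomy,
                           nonrigid_icp, rough_preregister, scale_to_template)
from .sections import HalfSpace, clip_mesh
from .template import AtlasTemplate, default_template
from .transforms import Line3, Plane3, unit


@dataclass
class _AffineMap:
    """Orthonormal (possibly improper, for mirroring) linear map + offset."""

    A: np.ndarray
    b: np.ndarray

    def apply(self, p):
        return np.asarray(p, dtype=float) @ self.A.T + self.b

    def apply_dir(self, d):
        return np.asarray(d, dtype=float) @ self.A.T

    def inverse(self) -> "_AffineMap":
        return _AffineMap(self.A.T, -self.A.T @ self.b)

    def compose(self, other: "_AffineMap") -> "_AffineMap":
        return _AffineMap(self.A @ other.A, self.A @ other.b + self.b)


@dataclass
class DetectionResult:
    anatomy: AnatomyResult                 # world coordinates
    frames: dict                           # name -> BoneFrame (world)
    side: str
    canonical_anatomy: AnatomyResult = field(repr=False, default=None)
    mapped_landmark_names: tuple = ()

    def to_dict(self) -> dict:
        d = self.anatomy.to_dict()
        d["side"] = self.side
        d["frames"] = {k: v.to_dict() for k, v in self.frames.items()}
        return d


def detect_anatomy(mesh: SurfaceMesh, side: str,
                   template: AtlasTemplate | None = None,
                   config: DetectConfig | None = None) -> DetectionResult:
    """Run the full two-stage detection and build the three bone frames."""
    cfg = config or DetectConfig()
    if side not in ("left", "right"):
        raise StageError("input", f"side must be left|right, got {side!r}")
    if template is None:
        template = default_template()

    # --- canonicalization: mirror left femora to right-side geometry
    mirror = side == "left"
    work = mesh.mirrored(axis=1) if mirror else mesh
    M = np.diag([1.0, -1.0, 1.0]) if mirror else np.eye(3)

    # --- stage 1: registration
    work_tfcs, T_tfcs = align_to_tfcs(work)
    scaled, s = scale_to_template(work_tfcs, template)
    R_pre = rough_preregister(scaled, template,
                              coarse_step_deg=cfg.prereg_coarse_step_deg,
                              fine_step_deg=cfg.prereg_fine_step_deg,
                              distal_fraction=cfg.prereg_distal_fraction)
    canon = work_tfcs.transformed(R_pre)
    canon_scaled = scaled.transformed(R_pre)
    dtpl, deform_diag = deform_template(
        template, canon_scaled,
        version_range=cfg.deform_version_range_deg,
        ccd_range=cfg.deform_ccd_range_deg,
        neck_frac_range=cfg.deform_neck_fraction_range,
        grid_step_deg=cfg.deform_grid_step_deg)
    registered, nicp_diag = nonrigid_icp(
        dtpl, canon_scaled,
        stiffness_steps=cfg.nicp_stiffness_steps,
        stiffness_start=cfg.nicp_stiffness_start,
        stiffness_factor=cfg.nicp_stiffness_factor,
        inner_iterations=cfg.nicp_inner_iterations,
        converged_residual=cfg.nicp_converged_residual)
    mapped = map_anatomy(registered.scaled(1.0 / s), template, canon)

    # world -> canonical affine (includes the optional mirror)
    F = _AffineMap(R_pre.rotation @ T_tfcs.rotation @ M,
                   R_pre.rotation @ T_tfcs.translation)

    # --- stage 2: refinement (canonical frame)
    tree = cKDTree(canon.vertices)
    regions = {}
    for name in ("head", "neck", "medial_condyle", "lateral_condyle"):
        regions[name] = _dilate(canon, tree, mapped.regions[name],
                                cfg.region_dilation_mm)

    result = AnatomyResult()
    diag = result.diagnostics
    diag["registration"] = {"scale": s, "deform": deform_diag, "nicp": nicp_diag}

    fhc, head_radius, diag["fhc"] = refine_fhc(regions["head"])
    shaft_axis, diag["shaft_axis"] = detect_shaft_axis(canon, fhc, cfg)
    neck_axis, diag["neck_axis"] = refine_neck_axis(canon, regions["neck"], fhc, cfg)
    mpc, lpc, ptc, ttp, diag["ttp"] = detect_ttp(
        canon, regions["medial_condyle"], regions["lateral_condyle"], neck_axis, cfg)

    x = canon.vertices[:, 0]
    cut = x.min() + cfg.usp_distal_fraction * (x.max() - x.min())
    distal = clip_mesh(canon, HalfSpace(Plane3([cut, 0.0, 0.0], [-1.0, 0.0, 0.0])))
    usp, pfea, cea, diag["usp"] = compute_usp(
        distal, regions["medial_condyle"], regions["lateral_condyle"], cfg)
    mec, lec, diag["epicondyles"] = detect_epicondyles(
        distal, usp.normal, cea, mapped.landmarks["MEC"], mapped.landmarks["LEC"], cfg)
    icn, diag["icn"] = detect_icn(distal, pfea, cfg)
    sgt, lt, diag["passthrough"] = passthrough_landmarks(mapped.landmarks)

    result.landmarks = {"FHC": fhc, "MEC": mec, "LEC": lec, "MPC": mpc,
                        "LPC": lpc, "PTC": ptc, "ICN": icn, "SGT": sgt, "LT": lt}
    result.axes = {"shaft": shaft_axis, "neck": neck_axis, "PFEA": pfea, "CEA": cea}
    result.planes = {"TTP": ttp, "USP": usp}
    diag["head_radius"] = head_radius

    # --- transport to world coordinates
    Fi = F.inverse()
    world = AnatomyResult(
        landmarks={k: Fi.apply(v) for k, v in result.landmarks.items()},
        axes={k: Line3(Fi.apply(v.point), unit(Fi.apply_dir(v.direction)))
              for k, v in result.axes.items()},
        planes={k: Plane3(Fi.apply(v.point), unit(Fi.apply_dir(v.normal)))
                for k, v in result.planes.items()},
        diagnostics=diag)

    frames = build_frames(world, side)
    return DetectionResult(anatomy=world, frames=frames, side=side,
                           canonical_anatomy=result,
                           mapped_landmark_names=("SGT", "LT"))


def build_frames(anatomy: AnatomyResult, side: str) -> dict:
    lm = anatomy.landmarks
    frames = {
        "Wu2002": build_wu2002(lm["FHC"], lm["MEC"], lm["LEC"], side),
        "Bergmann2016": build_bergmann2016(
            lm["FHC"], lm["MPC"], lm["LPC"], lm["ICN"],
            anatomy.axes["neck"], anatomy.axes["shaft"], side),
        "TableTop": build_tabletop(lm["FHC"], lm["MPC"], lm["LPC"],
                                   anatomy.planes["TTP"].normal, side),
    }
    return frames


def _dilate(mesh: SurfaceMesh, tree: cKDTree, region_points: np.ndarray,
            radius_mm: float) -> np.ndarray:
    """Densify a sparsely mapped region with all subject vertices within
    ``radius_mm`` of the mapped points (the template is usually coarser than
    the subject, so the raw mapping under-samples the region)."""
    if radius_mm <= 0:
        return region_points
    idx = tree.query_ball_point(region_points, radius_mm)
    flat = sorted({j for lst in idx for j in lst})
    if not flat:
        return region_points
    return mesh.vertices[np.asarray(flat, dtype=int)]
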