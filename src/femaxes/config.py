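"""Tunable parameters of the detection pipeline.

Every value the underlying publications leave unspecified is collected here
so the gap-filling decisions are visible and overridable.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class DetectConfig:
    # pre-registration
    prereg_coarse_step_deg: float = 10.0
    prereg_fine_step_deg: float = 5.0
    prereg_distal_fraction: float = 0.4

    # template deformation search
    deform_version_range_deg: float = 20.0
    deform_ccd_range_deg: float = 15.0
    deform_neck_fraction_range: float = 0.10
    deform_grid_step_deg: float = 5.0

    # nonrigid ICP
    nicp_stiffness_steps: int = 8
    nicp_stiffness_start: float = 50.0
    nicp_stiffness_factor: float = 0.55
    nicp_inner_iterations: int = 1
    nicp_converged_residual: float = 1.0

    # region transfer
    region_dilation_mm: float = 4.0

    # shaft axis
    shaft_keep_fraction: tuple = (0.25, 0.75)  # middle half along the diameter

    # neck axis search
    neck_angle_steps_deg: tuple = (2.0, 1.0, 0.5, 0.25, 0.1)
    neck_offset_step_mm: float = 2.0
    neck_tol_mm: float = 1e-4
    neck_max_iterations: int = 400

    # table-top plane fixed point
    ttp_rotation_tol_rad: float = 1e-6
    ttp_max_iterations: int = 50
    ttp_proximal_fraction: float = 0.30

    # unified sagittal plane
    usp_planes_per_condyle: int = 15
    usp_plane_span: tuple = (0.15, 0.85)
    usp_arc_half_angle_deg: float = 80.0
    usp_angle_steps_deg: tuple = (2.0, 1.0, 0.5, 0.25)
    usp_tol: float = 1e-6
    usp_max_iterations: int = 200
    usp_distal_fraction: float = 0.35

    # intercondylar notch
    icn_planes: int = 15
    icn_slab_margin: float = 0.05
    icn_curvature_window: int = 3
    icn_outline_bins: int = 40

    seed: int = 0

    def override(self, **kwargs) -> "DetectConfig":
        known = {f.name for f in fields(self)}
        bad = set(kwargs) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        out = DetectConfig(**{f.name: getattr(self, f.name) for f in fields(self)})
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out
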