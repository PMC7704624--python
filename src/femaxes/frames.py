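"""Femoral bone coordinate systems and frame comparison.

Three frames are constructed from the detected anatomy (origin always the
FHC): Wu2002 (epicondylar + mechanical axis), Bergmann2016 (posterior
condylar + straight femur axis) and TableTop (posterior condylar axis + TTP
normal).

Sign convention: the posteroanterior axis is anterior-positive and the
distoproximal axis proximal-positive on both sides; the mediolateral axis
completes the right-handed triad (lateral-positive on the right,
medial-positive on the left — a single triad cannot be mirror-symmetric and
right-handed at once).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FemaxesError
from .transforms import (Line3, RigidTransform, closest_point_between_lines,
                         euler_xyz_intrinsic_deg, random_rigid_transform, unit)

FRAME_NAMES = ("Wu2002", "Bergmann2016", "TableTop")


@dataclass(frozen=True)
class BoneFrame:
    """Origin (FHC) + right-handed orthonormal triad.

    ``axes`` rows are the mediolateral, posteroanterior and distoproximal
    unit vectors in world coordinates.
    """

    name: str
    origin: np.ndarray
    axes: np.ndarray  # rows: ML, PA, DP

    def __post_init__(self):
        A = np.asarray(self.axes, dtype=float).reshape(3, 3)
        o = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.allclose(A @ A.T, np.eye(3), atol=1e-9):
            raise FemaxesError("frame axes are not orthonormal")
        if abs(np.linalg.det(A) - 1.0) > 1e-9:
            raise FemaxesError("frame axes are not right-handed")
        object.__setattr__(self, "axes", A)
        object.__setattr__(self, "origin", o)

    @property
    def ml(self) -> np.ndarray:
        return self.axes[0]

    @property
    def pa(self) -> np.ndarray:
        return self.axes[1]

    @property
    def dp(self) -> np.ndarray:
        return self.axes[2]

    def transformed(self, T: RigidTransform) -> "BoneFrame":
        return BoneFrame(self.name, T.apply(self.origin), self.axes @ T.rotation.T)

    def to_dict(self) -> dict:
        return {"name": self.name,
                "origin": [float(x) for x in self.origin],
                "mediolateral": [float(x) for x in self.ml],
                "posteroanterior": [float(x) for x in self.pa],
                "distoproximal": [float(x) for x in self.dp]}


def _side_sign(side: str) -> float:
    if side not in ("left", "right"):
        raise FemaxesError(f"side must be left|right, got {side!r}")
    return 1.0 if side == "right" else -1.0


def _frame(name, origin, ml, pa, dp) -> BoneFrame:
    return BoneFrame(name, origin, np.stack([ml, pa, dp]))


def build_wu2002(fhc, mec, lec, side: str) -> BoneFrame:
    """Epicondylar axis (1st) + mechanical axis (2nd, kept exact as DP)."""
    fhc, mec, lec = (np.asarray(v, dtype=float) for v in (fhc, mec, lec))
    s = _side_sign(side)
    mid = 0.5 * (mec + lec)
    epi = lec - mec
    if np.linalg.norm(epi) < 1e-9 or np.linalg.norm(fhc - mid) < 1e-9:
        raise FemaxesError("Wu2002: degenerate landmark configuration")
    dp = unit(fhc - mid)
    pa_raw = np.cross(dp, epi)
    if np.linalg.norm(pa_raw) < 1e-9:
        raise FemaxesError("Wu2002: collinear landmarks")
    pa = s * unit(pa_raw)
    ml = np.cross(pa, dp)
    return _frame("Wu2002", fhc, ml, pa, dp)


def build_bergmann2016(fhc, mpc, lpc, icn, neck_axis: Line3, shaft_axis: Line3,
                       side: str) -> BoneFrame:
    """Posterior condylar axis (1st) + straight femur axis (2nd, kept exact):
    ICN to the neck-axis point closest to the shaft axis."""
    fhc, mpc, lpc, icn = (np.asarray(v, dtype=float) for v in (fhc, mpc, lpc, icn))
    s = _side_sign(side)
    p_star, _ = closest_point_between_lines(neck_axis, shaft_axis)
    if np.linalg.norm(p_star - icn) < 1e-9:
        raise FemaxesError("Bergmann2016: degenerate straight femur axis")
    dp = unit(p_star - icn)
    pca = lpc - mpc
    pa_raw = np.cross(dp, pca)
    if np.linalg.norm(pa_raw) < 1e-9:
        raise FemaxesError("Bergmann2016: condylar axis parallel to straight axis")
    pa = s * unit(pa_raw)
    ml = np.cross(pa, dp)
    return _frame("Bergmann2016", fhc, ml, pa, dp)


def build_tabletop(fhc, mpc, lpc, ttp_normal, side: str) -> BoneFrame:
    """Posterior condylar axis (1st) + TTP normal (2nd, kept exact as PA)."""
    fhc, mpc, lpc = (np.asarray(v, dtype=float) for v in (fhc, mpc, lpc))
    s = _side_sign(side)
    nrm = unit(ttp_normal)
    ml_raw = lpc - mpc
    if np.linalg.norm(ml_raw) < 1e-9:
        raise FemaxesError("TableTop: MPC equals LPC")
    ml_raw = unit(ml_raw)
    if abs(np.dot(ml_raw, nrm)) > 1.0 - 1e-9:
        raise FemaxesError("TableTop: TTP normal parallel to the condylar axis")
    prox_hint = fhc - 0.5 * (mpc + lpc)
    anterior_hint = s * np.cross(prox_hint, ml_raw)
    pa = nrm if np.dot(nrm, anterior_hint) >= 0 else -nrm
    ml = s * ml_raw
    ml = unit(ml - np.dot(ml, pa) * pa)
    dp = np.cross(ml, pa)
    return _frame("TableTop", fhc, ml, pa, dp)


@dataclass(frozen=True)
class FrameDifference:
    """Anatomical Euler angles (degrees) between two same-named frames."""

    adduction_abduction: float   # about the posteroanterior axis (x)
    internal_external: float     # about the distoproximal axis (y)
    flexion_extension: float     # about the mediolateral axis (z)
    gimbal: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.adduction_abduction, self.internal_external,
                         self.flexion_extension])

    def max_abs(self) -> float:
        return float(np.abs(self.as_array()).max())


def _comparison_matrix(frame: BoneFrame) -> np.ndarray:
    # ISB-style ordering: x anterior (PA), y proximal (DP), z mediolateral
    return np.stack([frame.pa, frame.dp, frame.ml])


def frame_difference(reference: BoneFrame, test: BoneFrame) -> FrameDifference:
    """Intrinsic x-y-z Euler decomposition of the rotation from the
    reference frame to the test frame."""
    if reference.name != test.name:
        raise FemaxesError("can only compare frames of the same name")
    Cr = _comparison_matrix(reference)
    Ct = _comparison_matrix(test)
    R = Cr @ Ct.T
    aa, ie, fe = euler_xyz_intrinsic_deg(R)
    gimbal = bool(abs(abs(R[0, 2]) - 1.0) < 1e-9)
    return FrameDifference(adduction_abduction=aa, internal_external=ie,
                           flexion_extension=fe, gimbal=gimbal)


def recompose_difference(diff: FrameDifference) -> np.ndarray:
    from .transforms import euler_xyz_to_matrix
    return euler_xyz_to_matrix(diff.adduction_abduction, diff.internal_external,
                               diff.flexion_extension)


# ------------------------------------------------------------- robustness

def robustness_check(mesh, side: str, template=None, n_transforms: int = 10,
                     seed: int = 0, config=None,
                     max_angle_deg: float = 360.0,
                     max_translation: float = 1000.0) -> dict:
    """Alignment-robustness harness.

    Runs the full pipeline on ``n_transforms`` seeded random rigid copies of
    the mesh, transports the results back, and reports the maximum landmark
    discrepancy and frame-difference angles relative to the untransformed
    baseline. Per-trial failures are recorded, not fatal.
    """
    from .pipeline import detect_anatomy  # deferred: avoid import cycle

    if n_transforms < 1:
        raise FemaxesError("n_transforms must be >= 1")
    rng = np.random.default_rng(seed)
    base = detect_anatomy(mesh, side, template=template, config=config)
    trials = []
    max_disc = 0.0
    max_angle = 0.0
    for k in range(n_transforms):
        T = random_rigid_transform(rng, max_angle_deg, max_translation)
        trial = {"index": k}
        try:
            res = detect_anatomy(mesh.transformed(T), side, template=template,
                                 config=config)
            Ti = T.inverse()
            disc = {}
            for name, p in res.anatomy.landmarks.items():
                back = Ti.apply(p)
                disc[name] = float(np.linalg.norm(back - base.anatomy.landmarks[name]))
            fr_ang = {}
            for name, f in res.frames.items():
                fd = frame_difference(base.frames[name], f.transformed(Ti))
                fr_ang[name] = fd.max_abs()
            trial["landmark_discrepancy_mm"] = disc
            trial["frame_difference_deg"] = fr_ang
            trial["max_landmark_discrepancy_mm"] = max(disc.values())
            trial["max_frame_difference_deg"] = max(fr_ang.values())
            max_disc = max(max_disc, trial["max_landmark_discrepancy_mm"])
            max_angle = max(max_angle, trial["max_frame_difference_deg"])
            trial["status"] = "ok"
        except Exception as exc:  # per-trial failures are recorded
            trial["status"] = "failed"
            trial["error"] = f"{type(exc).__name__}: {exc}"
        trials.append(trial)
    n_ok = sum(1 for t in trials if t["status"] == "ok")
    return {"n_transforms": n_transforms, "seed": seed, "n_ok": n_ok,
            "max_landmark_discrepancy_mm": max_disc,
            "max_frame_difference_deg": max_angle,
            "trials": trials}
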