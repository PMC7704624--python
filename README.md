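# femaxes

Fully automatic, alignment-robust detection of femoral landmarks, axes and
planes on 3D bone surface models, and construction of three femoral bone
coordinate systems (Wu2002, Bergmann2016, TableTop). The method is a
two-stage atlas + a-priori-knowledge approach:

1. **Registration** — the subject mesh is moved to its principal axes of
   inertia, scaled and roughly pre-registered to an annotated template,
   the template's neck pose (version, CCD angle, neck length) is fitted by
   linear-blend-skinning deformation, and a locally affine nonrigid ICP
   registers the template to the subject. Template landmarks and regions are
   then mapped to the subject surface.
2. **Refinement** — the femoral head center (sphere fit), shaft axis
   (ellipsoid fit of the middle half), neck axis (minimal cutting-contour
   perimeter), table-top plane (posterior contact-point fixed point),
   unified sagittal plane / PFEA / CEA (posterior-foci dispersion
   minimization), epicondyles (three-candidate selection with an osteophyte
   guard) and intercondylar notch (curvature + frontal-silhouette rule) are
   refined from the mapped anatomy.

A parametric **synthetic femur generator** (smoothly blended implicit
primitives, marching-cubes extraction, exact analytic ground truth) provides
both the packaged atlas template and ground-truth test subjects. All mesh
I/O (STL ASCII/binary, PLY ASCII/binary-little-endian, OBJ), geometry and
fitting primitives are implemented in the package on top of
numpy/scipy/shapely/scikit-image.

Coordinates are millimetres. Input meshes must be closed surfaces of a
complete femur; the side (`left`/`right`) must be given — it is not
auto-detected.

## CLI

```sh
# generate a synthetic femur (+ ground-truth JSON); --template also writes
# the atlas annotation sidecar
femaxes generate -o femur.ply --ccd 125 --version 15

# detect landmarks, axes, planes, frames (any input pose)
femaxes detect femur.ply --side right -o anatomy.json

# alignment-robustness harness (random rigid transforms, re-detection)
femaxes robustness femur.ply --side right -n 10 --seed 0 -o report.json
```

All pipeline tolerances and step sizes live in one config namespace
(`femaxes.config.DetectConfig`); override with `--set key=value` or a
`key = value` config file via `--config`.

## Python API

```python
from femaxes import detect_anatomy, generate_femur, default_spec

mesh, gt = generate_femur(default_spec(ccd_angle=130, version_angle=20))
result = detect_anatomy(mesh, side="right")
result.anatomy.landmarks["FHC"]      # 3D points (mm)
result.frames["Wu2002"].axes         # rows: mediolateral, posteroanterior,
                                     # distoproximal unit vectors
```

## Notes and limitations

- Left femora are handled by mirroring to a canonical right-side pose and
  mirroring the results back; frames use per-side sign conventions
  (posteroanterior anterior-positive and distoproximal proximal-positive on
  both sides; the mediolateral axis completes the right-handed triad).
- Large osteophytes at the femoral neck can misalign the neck axis; this is
  a known limitation of the method, not handled here.
- Partial femora are not supported; the registration needs the full bone.
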