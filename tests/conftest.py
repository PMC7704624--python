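import numpy as np
import pytest

from femaxes.pipeline import detect_anatomy
from femaxes.synthetic import default_spec, generate_femur
from femaxes.template import default_template


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def default_case():
    """Default synthetic femur with its ground truth."""
    spec = default_spec()
    mesh, gt = generate_femur(spec)
    return spec, mesh, gt


@pytest.fixture(scope="session")
def varied_case():
    """A femur dissimilar from the template in CCD, version and length."""
    spec = default_spec(ccd_angle=130.0, version_angle=20.0, total_length=470.0,
                        neck_length=60.0)
    mesh, gt = generate_femur(spec)
    return spec, mesh, gt


@pytest.fixture(scope="session")
def default_result(default_case, template):
    _, mesh, _ = default_case
    return detect_anatomy(mesh, "right", template=template)


@pytest.fixture(scope="session")
def varied_result(varied_case, template):
    _, mesh, _ = varied_case
    return detect_anatomy(mesh, "right", template=template)


@pytest.fixture(scope="session")
def mirrored_pair(template):
    """Left/right femora of a mirrored spec with their detection results."""
    spec_r = default_spec(ccd_angle=128.0, version_angle=18.0)
    spec_l = spec_r.mirrored()
    mesh_r, gt_r = generate_femur(spec_r)
    mesh_l, gt_l = generate_femur(spec_l)
    res_r = detect_anatomy(mesh_r, "right", template=template)
    res_l = detect_anatomy(mesh_l, "left", template=template)
    return (mesh_r, gt_r, res_r), (mesh_l, gt_l, res_l)


def angle_deg(a, b, directed: bool = False) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = a @ b if directed else abs(a @ b)
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))
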