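import numpy as np
import pytest

import mribulk as mb


@pytest.fixture(scope="session")
def head_phantom():
    """Default implant-free head phantom (labels, ct, mri, structures)."""
    return mb.make_head_phantom(seed=1)


@pytest.fixture(scope="session")
def implant_phantom():
    cfg = mb.HeadPhantomConfig(with_implants=True)
    return mb.make_head_phantom(cfg, seed=1)


@pytest.fixture(scope="session")
def grid_truth():
    """Default undistorted grid phantom."""
    return mb.make_grid_phantom()


@pytest.fixture(scope="session")
def water_cylinder():
    """Water cylinder with a central PTV70 and a posterior OAR surrogate."""
    vol = mb.centered_grid((60, 60, 40), (4, 4, 4))
    xs, ys, zs = np.broadcast_arrays(*vol.coordinate_grids())
    body = np.hypot(xs, ys) <= 100
    ptv = (np.hypot(xs, ys) <= 20) & (np.abs(zs) <= 30)
    oar = (np.hypot(xs, ys - 45) <= 8) & (np.abs(zs) <= 40)
    structs = mb.StructureSet(
        {"BODY": body, "PTV70": ptv & body, "brainstem": oar & body},
        vol.spacing_mm,
        vol.origin_mm,
    )
    red = vol.like(np.where(body, 1.0, 0.0).astype(np.float32))
    return red, structs


@pytest.fixture(scope="session")
def optimized_water_plan(water_cylinder):
    red, structs = water_cylinder
    skeleton = mb.Plan(
        [mb.BeamSpec(a, n_u=12, n_v=18, beamlet_mm=5.0) for a in mb.default_beam_angles()],
        prescriptions_gy={"PTV70": 70.0},
    )
    obj = mb.Objectives(target_rx_gy={"PTV70": 70.0}, oar_max_gy={"brainstem": 54.0})
    return mb.optimize_fluence(skeleton, structs, red, obj, seed=1)


def mask_points(structs, mask):
    idx = np.argwhere(mask)
    return structs.origin_mm + idx * structs.spacing_mm
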