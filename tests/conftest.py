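import numpy as np
import pytest

from fluoropose import (
    BackgroundConfig,
    LandmarkPlacement,
    PatchSpec,
    Pose,
    ProjectionGeometry,
    make_fiducial,
    render_radiograph,
)


@pytest.fixture(scope="session")
def geom():
    """Spec-nominal geometry: 2 px/mm at 1000 mm depth."""
    return ProjectionGeometry(d_sdd=1000.0, delta_ds=0.5, width=1024, height=1024)


@pytest.fixture(scope="session")
def geom_small():
    return ProjectionGeometry(d_sdd=1000.0, delta_ds=0.5, width=256, height=256)


@pytest.fixture(scope="session")
def placement():
    return LandmarkPlacement()


@pytest.fixture(scope="session")
def patch_spec():
    return PatchSpec()


@pytest.fixture(scope="session")
def screw():
    return make_fiducial("screw")


@pytest.fixture(scope="session")
def rendered_screw(screw, geom_small):
    """One clean screw radiograph at a known pose."""
    pose = Pose(x=130.0, y=120.0, alpha=30.0, tau=25.0, d=900.0)
    image = render_radiograph(screw, pose, geom_small, BackgroundConfig.clean())
    return image, pose


def random_pose(rng: np.random.Generator, geom, tau_max=80.0) -> Pose:
    return Pose(
        x=float(rng.uniform(0.2 * geom.width, 0.8 * geom.width)),
        y=float(rng.uniform(0.2 * geom.height, 0.8 * geom.height)),
        alpha=float(rng.uniform(-180.0, 180.0)),
        tau=float(rng.uniform(-tau_max, tau_max)),
        d=float(rng.uniform(850.0, 950.0)),
    )
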