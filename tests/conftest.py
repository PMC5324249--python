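import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vesselgauge as vg

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class PhantomCase:
    """Phantom + ground truth + (lazily computed) centerline."""

    def __init__(self, name, **overrides):
        self.spec = vg.preset(name, **overrides)
        self.mesh, self.truth = vg.make_open_phantom(self.spec)
        self._cl = None

    @property
    def centerline(self):
        if self._cl is None:
            self._cl = vg.compute_centerline(
                self.mesh,
                self.truth.centerline_points[0],
                self.truth.centerline_points[-1],
            )
        return self._cl


@pytest.fixture(scope="session")
def cylinder_case():
    return PhantomCase("cylinder")


@pytest.fixture(scope="session")
def arch_case():
    return PhantomCase("arch")


@pytest.fixture(scope="session")
def coarctation_case():
    return PhantomCase("coarctation")


@pytest.fixture(scope="session")
def branched_case():
    return PhantomCase("branched")


@pytest.fixture(scope="session")
def cylinder_profile(cylinder_case):
    return vg.measure_profile(cylinder_case.mesh, cylinder_case.centerline)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


@pytest.fixture
def rigid_motion():
    return vg.RigidTransform(
        rotation_matrix([0.3, 1.0, 0.2], np.deg2rad(25.0)), [12.0, -7.0, 4.0]
    )
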