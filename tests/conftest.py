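import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from arnav import Pose, RigidTransform, compose, invert


def random_rigid(rng: np.random.Generator, from_frame="a", to_frame="b", t_scale=100.0):
    """Uniformly random proper rigid transform."""
    rot = Rotation.random(random_state=rng).as_matrix()
    return RigidTransform(rot, rng.normal(0.0, t_scale, 3), from_frame, to_frame)


def rotz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def sensor_pose_for(model, projector_to_world: RigidTransform) -> Pose:
    """Tracked sensor pose that puts the projector at the given world pose."""
    return Pose("sensor", compose(projector_to_world, invert(model.t_sensor_to_projector)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
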