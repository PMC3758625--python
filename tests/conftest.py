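import numpy as np
import pytest

from kinfilter import build_default_model, neutral_pose
from kinfilter import ik_solver


@pytest.fixture(scope="session")
def model():
    return build_default_model(1750.0)


@pytest.fixture(scope="session")
def neutral(model):
    return neutral_pose(model)


@pytest.fixture(scope="session")
def full_obstacles(model, neutral):
    """Static torso/head proxies plus the neutral left arm, for single-arm solves."""
    return ik_solver.static_obstacles(model) + ik_solver._arm_geoms(
        model,
        "l",
        model.shoulder_position("l"),
        neutral.joint_positions["l_elbow"],
        neutral.joint_positions["l_hand"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_reachable_target(rng, model, side="r", margin=5.0):
    l_ua, l_fa = model.arm_lengths(side)
    d = rng.uniform(abs(l_ua - l_fa) + margin, l_ua + l_fa - margin)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return model.shoulder_position(side) + d * v
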