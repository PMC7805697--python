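import numpy as np
import pytest

from ethotank.arena import make_default_arena
from ethotank.records import Trajectory
from ethotank.swim_sim import SwimParams


@pytest.fixture(scope="session")
def arena():
    return make_default_arena()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def swim_params():
    return SwimParams(seed=42)


def random_focal_trajectory(rng, n=200, dt=0.05, step_sd=0.6,
                            with_flags=False):
    """Random-walk trajectory confined to the focal compartment."""
    steps = rng.normal(0.0, step_sd, size=(n, 2))
    xy = np.cumsum(steps, axis=0) + [15.0, 15.0]
    # reflect into [0.01, 29.99]^2 to stay strictly inside
    xy = np.abs(xy)
    xy = 29.98 - np.abs(29.98 - xy % 59.96) + 0.01
    traj = Trajectory.from_positions(xy, dt=dt)
    if with_flags:
        interp = rng.random(n) < 0.1
        traj.interpolated = interp
    return traj


@pytest.fixture
def focal_traj_factory(rng):
    def make(**kw):
        return random_focal_trajectory(rng, **kw)
    return make
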