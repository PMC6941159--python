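import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dogmotion.trajectory import Trajectory

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_trajectory(points, frame_rate=5.0, units="cm", valid=None):
    """Trajectory from an (n, 2) point array at a uniform frame rate."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return Trajectory(
        frames=np.arange(n),
        times=np.arange(n) / frame_rate,
        x=pts[:, 0],
        y=pts[:, 1],
        valid=np.asarray(valid, dtype=bool),
        frame_rate=frame_rate,
        units=units,
    )


@pytest.fixture
def straight_track():
    """Constant velocity 10 cm/s along +x for 180 s at 5 Hz."""
    t = np.arange(0, 180.0 + 1e-9, 0.2)
    pts = np.column_stack([10.0 * t, np.zeros_like(t)])
    return make_trajectory(pts, frame_rate=5.0)


@pytest.fixture
def square_track():
    """Perimeter of a 100 cm square, traversed once, closed."""
    side = np.linspace(0, 100, 26)
    pts = np.concatenate(
        [
            np.column_stack([side, np.zeros_like(side)]),
            np.column_stack([np.full_like(side[1:], 100.0), side[1:]]),
            np.column_stack([side[::-1][1:], np.full_like(side[1:], 100.0)]),
            np.column_stack([np.zeros_like(side[1:]), side[::-1][1:]]),
        ]
    )
    return make_trajectory(pts, frame_rate=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_walk(rng, n=50, step=5.0):
    """Random open 2-D walk used as a generic irregular polyline."""
    steps = rng.normal(scale=step, size=(n - 1, 2))
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
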