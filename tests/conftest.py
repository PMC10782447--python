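import numpy as np
import pytest

from disolv.md import Trajectory
from disolv.system import make_system


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def traj_factory():
    """Build a Trajectory directly from raw frame arrays (no MD)."""

    def _make(frames, species, box, times=None, charges=None, mobile=None,
              ml_visible=None, images=None):
        frames = np.asarray(frames, float)
        template = make_system(frames[0], species, box, charges=charges,
                               mobile=mobile, ml_visible=ml_visible)
        n_f, n_p = frames.shape[0], frames.shape[1]
        if times is None:
            times = np.arange(n_f, dtype=float)
        if images is None:
            images = np.zeros((n_f, n_p, 3), np.int64)
        return Trajectory(positions=frames, images=images,
                          times=np.asarray(times, float), template=template)

    return _make


@pytest.fixture()
def small_nacl_system(rng):
    """16-ion box with no hard overlaps, for force/energy checks."""
    from disolv.validate import random_ionic_configurations
    return random_ionic_configurations(1, n_ions=16, box_edge=3.0, seed=7)[0]
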