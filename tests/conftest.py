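import numpy as np
import pytest

from swayfractal import CopTrajectory, SyntheticSpec, generate_cop2d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_walk_traj(rng):
    """100-point seeded 2-D random walk at 100 Hz."""
    steps = rng.standard_normal((99, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return CopTrajectory(x=xy[:, 0], y=xy[:, 1], sample_rate=100.0)


@pytest.fixture
def small_cop_trial():
    """Short synthetic COP trial, cheap enough for unit tests."""
    return generate_cop2d(SyntheticSpec(n=4096, sample_rate=1000.0, seed=11))
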