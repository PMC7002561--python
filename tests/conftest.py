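import numpy as np
import pytest

from vasovol.phantom import PhantomSpec, TubeSpec, generate_phantom_volume
from vasovol.recon import ImageVolume


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Noise-free cylinder r = 2 mm, L = 40 mm at 0.25 mm spacing, with the
    axis in generic (off-lattice) position."""
    tube = TubeSpec(
        control_points=((6.1, 6.07, 2.0), (6.1, 6.07, 42.0)),
        baseline_radius=2.0,
        segment_label="M1",
    )
    spec = PhantomSpec(grid_shape=(48, 48, 180), spacing=(0.25, 0.25, 0.25), tubes=(tube,))
    volume, truth = generate_phantom_volume(spec)
    return spec, ImageVolume(volume, spec.spacing), truth


@pytest.fixture(scope="session")
def narrowed_tube_phantom():
    """Noise-free tube with 50% diameter narrowing over its distal half."""
    tube = TubeSpec(
        control_points=((6.0, 6.0, 5.0), (6.0, 6.0, 85.0)),
        baseline_radius=2.0,
        narrowing_factor=0.5,
        narrowing_span=(40.0, 80.0),
        segment_label="M1",
    )
    spec = PhantomSpec(grid_shape=(48, 48, 380), spacing=(0.25, 0.25, 0.25), tubes=(tube,))
    volume, truth = generate_phantom_volume(spec)
    return spec, ImageVolume(volume, spec.spacing), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
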