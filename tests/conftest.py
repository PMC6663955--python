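import numpy as np
import pytest

from spectenh.core import GridSpec
from spectenh.phantom import TorsoPhantomSpec, make_torso_phantom
from spectenh.projector import DetectorConfig


@pytest.fixture(scope="session")
def torso64():
    """Default desk-scale torso phantom ground truth (64^3 at 7.8 mm)."""
    return make_torso_phantom(TorsoPhantomSpec(), GridSpec())


@pytest.fixture(scope="session")
def torso32():
    """Coarse torso phantom for fast projection/reconstruction tests."""
    return make_torso_phantom(
        TorsoPhantomSpec(), GridSpec(32, 32, 32, voxel_size=15.6)
    )


@pytest.fixture()
def small_detector():
    """Few-angle detector configuration for operator-level tests."""
    return DetectorConfig(n_angles=4, scan_time_s=10.0, sensitivity=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
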