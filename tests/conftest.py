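import numpy as np
import pytest

from batrack.geometry import CalibrationTarget, StereoRig


@pytest.fixture(scope="session")
def rig() -> StereoRig:
    """Default field geometry: 640x480, 33 deg lenses, 4 m baseline, parallel."""
    return StereoRig.default()


@pytest.fixture(scope="session")
def converged_rig() -> StereoRig:
    """Slightly toed-in rig giving a wide joint field of view for recovery tests."""
    return StereoRig.default(pan_deg=8.0)


@pytest.fixture(scope="session")
def target() -> CalibrationTarget:
    return CalibrationTarget()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
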