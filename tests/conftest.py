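"""Shared fixtures: small seeded synthetic scenes and camera models."""

import numpy as np
import pytest

from otoar import (
    CameraIntrinsics,
    InstrumentModel,
    SceneSpec,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def static_ds():
    """Tiny static scene: 2 s at 12 fps, 6 fiducials, default texture."""
    return simulate_dataset(SceneSpec.preset_static(1, duration_s=2.0))


@pytest.fixture(scope="session")
def registration_ds():
    """Single-frame scene at a seeded off-reference pose."""
    return simulate_dataset(SceneSpec.preset_registration(3))


@pytest.fixture(scope="session")
def bench_intrinsics():
    """Microscope camera analog used in the instrument experiments."""
    return CameraIntrinsics(5000.0, (640.0, 512.0), (1280, 1024))


@pytest.fixture(scope="session")
def tool_model():
    return InstrumentModel.from_spacings(3.0, 3.0, 3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
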