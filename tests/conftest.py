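import numpy as np
import pytest

from standmetrics.geometry import CameraIntrinsics
from standmetrics.synthetic_field import DESK_INTRINSICS, AcquisitionConfig, StandConfig


@pytest.fixture
def intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics(fx=1000.0, fy=1000.0, cx=550.0, cy=310.0, width=1100, height=620)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def desk_acquisition(**overrides) -> AcquisitionConfig:
    """Desk-scale survey pass: small render, 5 fps, otherwise field defaults."""
    base = dict(intrinsics=DESK_INTRINSICS, rgb_rate=5.0, depth_rate=5.0, seed=0)
    base.update(overrides)
    return AcquisitionConfig(**base)


def noiseless_stand(n_positions: int = 50, **overrides) -> StandConfig:
    base = dict(
        target_spacing=0.20,
        n_positions=n_positions,
        p_miss=0.0,
        p_multiple=0.0,
        spacing_sd=0.0,
        cross_track_sd=0.0,
        plant_height_sd=0.0,
        seed=0,
    )
    base.update(overrides)
    return StandConfig(**base)
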