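import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voxelbridge as vb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def unit_transform():
    """1 cm/voxel, corner at the origin: world coords = (index + 0.5)/100."""
    return vb.SceneTransform(
        vb.UnitMode.PX_TO_CM,
        vb.CenterMode.CORNER_ORIGIN,
        (0.01, 0.01, 0.01),
        (0.0, 0.0, 0.0),
    )


@pytest.fixture
def ball_phantom():
    spec = vb.PhantomSpec(kind="ball", shape_zyx=(32, 32, 32), radius=10, seed=3)
    volume, truth = vb.make_phantom(spec)
    return spec, volume, truth


@pytest.fixture
def ball_store(tmp_path, ball_phantom):
    _, volume, _ = ball_phantom
    path = tmp_path / "ball.zarr"
    vb.write_synthetic_store(volume, path, n_levels=3, axes="tczyx")
    return path


def make_levels(shapes, n_channels):
    """Pyramid metadata from a list of (z, y, x) shapes, finest first."""
    return [
        vb.MultiscaleLevel.from_shape(i, s, shapes[0], n_channels)
        for i, s in enumerate(shapes)
    ]
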