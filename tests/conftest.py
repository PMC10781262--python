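"""Shared fixtures: the default humanoid and its frontal depth map.

Expensive artefacts (mesh construction, 512x512 rasterisation, landmark
detection) are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from anthromesh import (
    CameraConfig,
    detect_seed_points,
    render_depth_map,
)
from anthromesh.projection import DepthMap
from anthromesh.synth_body import make_humanoid, make_primitive


@pytest.fixture(scope="session")
def humanoid():
    """Default A-pose humanoid (mesh, ground truth)."""
    return make_humanoid()


@pytest.fixture(scope="session")
def frontal_dm(humanoid):
    mesh, _ = humanoid
    return render_depth_map(mesh, CameraConfig(), 512, 512)


@pytest.fixture(scope="session")
def seeds(frontal_dm):
    return detect_seed_points(frontal_dm)


@pytest.fixture(scope="session")
def cylinder256():
    """Right cylinder r=100 mm, h=300 mm, 256-gon profile, plus ground truth."""
    return make_primitive("cylinder", dict(radius=100.0, height=300.0), 256)


def synthetic_depth_map(mask: np.ndarray, depth_mm: float = 3000.0) -> DepthMap:
    """Wrap a boolean silhouette mask into a DepthMap at constant depth.

    Used for phantom silhouettes (bars, rectangles) that exercise the
    landmark rules without a mesh or a renderer.
    """
    pixels = np.where(mask, 200, 0).astype(np.uint8)
    world_depth = np.where(mask, depth_mm, np.nan)
    return DepthMap(
        pixels=pixels,
        camera=CameraConfig(),
        world_depth=world_depth,
        pivot=np.zeros(3),
    )
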