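"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from rgbmocap.scene_simulator import RigParams, make_rig, make_scene


@pytest.fixture(scope="session")
def default_rig():
    return make_rig(RigParams())


@pytest.fixture(scope="session")
def scene():
    """Default capture session: 8-camera ring, 25 gait markers, wand sweep."""
    return make_scene(0, wand_frames=60)


@pytest.fixture(scope="session")
def scene_cameras(scene):
    return {c.id: c for c in scene.cameras}


@pytest.fixture(scope="session")
def background():
    """A textured synthetic background frame standing in for a non-marker trial."""
    rng = np.random.default_rng(7)
    base = rng.integers(40, 200, (30, 40, 3))
    from PIL import Image

    img = np.asarray(
        Image.fromarray(base.astype(np.uint8)).resize((640, 480), Image.BICUBIC)
    )
    noise = rng.integers(-12, 13, img.shape)
    return np.clip(img.astype(int) + noise, 0, 255).astype(np.uint8)
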