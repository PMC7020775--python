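import numpy as np
import pytest

import tileseg as ts


@pytest.fixture(scope="session")
def blob_image():
    """A 64x64 single-channel image with a noisy disc and its binary mask."""
    rng = np.random.default_rng(5)
    yy, xx = np.mgrid[0:64, 0:64]
    gt = ((yy - 30) ** 2 + (xx - 34) ** 2 <= 12**2).astype(np.uint8)
    image = gt * 1.5 + 0.1 * rng.random((64, 64))
    return image, gt


@pytest.fixture(scope="session")
def same_pad_model():
    """Seeded depth-2 same-padded model with instance norm (rich binary output)."""
    return ts.build_unet(ts.UNetConfig(depth=2, in_channels=1, seed=3, norm="instance"))


@pytest.fixture(scope="session")
def pointwise_model():
    """Depth-0, kernel-1 model: purely per-pixel, the stitching/equivariance oracle."""
    return ts.build_unet(ts.UNetConfig(depth=0, kernel=1, pad_mode="valid", in_channels=1, seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A 160x160 building scene with 12 rectangles including one cul-de-sac row."""
    cfg = ts.SceneConfig(
        image_size=(160, 160),
        n_buildings=12,
        building_size_range=(8, 20),
        min_gap=5,
        cul_de_sac_count=1,
        cul_de_sac_size=6,
        cluster_gap=3,
        seed=1,
    )
    return ts.make_building_scene(cfg)
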