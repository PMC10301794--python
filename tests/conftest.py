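import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def gray_scene_image(rng):
    """Linear RGB image of a gray-dominated scene with near-neutral spread.

    60% of pixels cluster tightly around the neutral gamut point; the rest
    spread along the warm/cool axis (neutral surfaces under varied local
    illumination), which is what lets the white-balance loop bootstrap
    from strong casts.
    """
    from torsomark.config import GamutTarget

    target = GamutTarget()
    tc = np.array([target.r, target.g, target.b])
    n = 12000
    nc = int(n * 0.6)
    cluster = tc + rng.normal(0, 0.005, size=(nc, 3))
    t = rng.uniform(-0.3, 0.3, size=n - nc)
    broad = np.stack([tc[0] + t, np.full(n - nc, tc[1]), tc[2] - t], axis=1)
    broad += rng.normal(0, 0.01, size=broad.shape)
    chrom = np.clip(np.concatenate([cluster, broad]), 0.01, None)
    chrom /= chrom.sum(axis=1, keepdims=True)
    intensity = rng.uniform(0.7, 1.3, size=n)  # keeps every channel below 1
    return (chrom * intensity[:, None]).reshape(100, 120, 3)
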