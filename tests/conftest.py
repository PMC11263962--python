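import sys
from pathlib import Path

import numpy as np
import pytest

from tomopick.io import Tomogram

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_tomogram(rng):
    return Tomogram(rng.normal(size=(24, 24, 24)).astype(np.float32), pixel_size=2.0)


def make_sphere_volume(shape_zyx, centers_zyx, radius, depth, noise_sigma=0.0, seed=0):
    """Small helper: cosine-tapered dark spheres on a flat background."""
    from tomopick.synth import _paint_sphere

    vol = np.zeros(shape_zyx, dtype=np.float64)
    for c in centers_zyx:
        _paint_sphere(vol, c, radius, depth)
    if noise_sigma:
        vol += np.random.default_rng(seed).normal(0, noise_sigma, shape_zyx)
    return vol.astype(np.float32)
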