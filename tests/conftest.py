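import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from specspat import HyperCube, LabelMap, SceneSpec, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cube(rng):
    return HyperCube(values=rng.uniform(0, 1, size=(5, 6, 4)))


@pytest.fixture
def tiny_scene():
    """Well-separated 3-class 24x24 scene with a little noise."""
    spec = SceneSpec(m=24, n=24, d=12, k=3, class_separation=12.0,
                     noise_sd=0.05, seed=7)
    return make_scene(spec)


@pytest.fixture
def checkerboard_labels():
    lab = np.ones((6, 6), dtype=np.int32)
    lab[3:, :] = 2
    return LabelMap(lab)
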