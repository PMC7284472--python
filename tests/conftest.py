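import numpy as np
import pytest

import weedvision as wv


@pytest.fixture(scope="session")
def small_scene():
    """One rendered stereo pair with 2 objects per class."""
    cfg = wv.SceneConfig(frame_size=(240, 320), n_objects_per_class=(2, 2, 2),
                         disparity_px=10, seed=11)
    left, right, truth = wv.generate_scene(cfg)
    return cfg, left, right, truth


@pytest.fixture(scope="session")
def segmented_scene(small_scene):
    cfg, left, right, truth = small_scene
    _, objects = wv.segment_frame(left, frame_id="f0", channel="left")
    return left, truth, objects


@pytest.fixture(scope="session")
def synthetic_table():
    """Well-separated table: 3 informative among 13 columns."""
    return wv.generate_feature_table(150, 3, 10, 8.0, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
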