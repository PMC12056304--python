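import numpy as np
import pytest

from plaquemetrics import segmentation, synthetic


@pytest.fixture(scope="session")
def default_profile():
    return synthetic.default_stain_profile()


@pytest.fixture(scope="session")
def noiseless_scene():
    """25-plaque noiseless scene shared by recovery tests."""
    spec = synthetic.SceneSpec(n_plaques=25, seed=7, noise_sd=0.0)
    scene, gt = synthetic.generate_scene(spec)
    return scene, gt


@pytest.fixture(scope="session")
def default_params():
    return segmentation.SegmentationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
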