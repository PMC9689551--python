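import numpy as np
import pytest

from ricedom import synth
from ricedom.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_scan():
    """One deterministic 12-grain scan with ground truth."""
    spec = synth.ScanSpec(image_height=700, image_width=900, n_grains=12, seed=7)
    img, truths = synth.render_scan(spec)
    return spec, img, truths


@pytest.fixture(scope="session")
def preprocess_cfg():
    return PreprocessConfig()
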