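import numpy as np
import pytest

from embryofuse import phantom, reporter


@pytest.fixture(scope="session")
def kb():
    return reporter.load_knowledge()


@pytest.fixture(scope="session")
def uniform_dataset():
    """21 phantoms (3 per class) at 64 px — shared by training-path tests."""
    props = {c: 1.0 / len(phantom.CLASSES) for c in phantom.CLASSES}
    return phantom.make_dataset(21, proportions=props, seed=3, image_size=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
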