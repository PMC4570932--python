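import numpy as np
import pytest

from mitoloc.surface import load_default_table


@pytest.fixture(scope="session")
def table():
    """The calibrated surface-class table shipped with the package."""
    return load_default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def random_blob_mask(rng, shape=(8, 8, 8), p=0.4):
    """Random boolean volume for oracle comparisons."""
    return rng.random(shape) < p
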