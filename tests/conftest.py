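import numpy as np
import pytest

from liverquant.phantom import PhantomSpec, build_phantom
from liverquant.signal_models import default_protocol_metas


@pytest.fixture(scope="session")
def metas():
    return default_protocol_metas()


@pytest.fixture(scope="session")
def phantom():
    """Default digital liver phantom (>=500 parenchyma voxels)."""
    ph = build_phantom(PhantomSpec(seed=7))
    assert ph.parenchyma_mask.sum() >= 500
    return ph


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
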