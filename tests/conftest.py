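import numpy as np
import pytest

import ordmisfit as om


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trio_pedigree():
    """Two founders and their offspring."""
    return om.Pedigree(sire=[0, 0, 1], dam=[0, 0, 2])


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small miscoded replicate shared by fast model-level tests."""
    cfg = om.scale_config(om.d2_config(misclass="symmetric"), 0.25)
    return om.simulate_dataset(cfg, seed=7)
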