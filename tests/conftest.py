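import numpy as np
import pytest

import connectocomm as cc


@pytest.fixture(scope="session")
def coords68():
    return cc.generate_geometry(68, seed=7)


@pytest.fixture(scope="session")
def template68(coords68):
    return cc.generate_connectome_template(coords68, target_density=0.25,
                                           decay_mm=30.0, seed=11)


@pytest.fixture(scope="session")
def battery68(template68, coords68):
    return cc.communication_battery(template68, coords68, density=0.20)


@pytest.fixture(scope="session")
def coords20():
    return cc.generate_geometry(20, seed=3)


@pytest.fixture(scope="session")
def template20(coords20):
    return cc.generate_connectome_template(coords20, target_density=0.3,
                                           decay_mm=40.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
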