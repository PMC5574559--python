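import numpy as np
import pytest

from laternula_deb import ScenarioConfig, default_params, default_site_f


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def site_f():
    return default_site_f()


@pytest.fixture(scope="session")
def f_map(site_f):
    return {"MC": site_f["f_MC"], "PC": site_f["f_PC"], "R": site_f["f_R"]}


@pytest.fixture()
def scenario():
    return ScenarioConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
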