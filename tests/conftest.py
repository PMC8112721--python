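import numpy as np
import pytest

from tsg import SineWeibull, TransformedSinWeibull, load_dataset, make_baseline


@pytest.fixture(scope="session")
def tensile():
    return load_dataset("carbon_fibers_tensile").values


@pytest.fixture(scope="session")
def breaking():
    return load_dataset("carbon_fibers_breaking").values


@pytest.fixture(scope="session")
def tsw_fit_tensile(tensile):
    return TransformedSinWeibull(tensile).fit(seed=0)


@pytest.fixture(scope="session")
def tsw_fit_breaking(breaking):
    return TransformedSinWeibull(breaking).fit(seed=0)


@pytest.fixture(scope="session")
def sw_fit_tensile(tensile):
    return SineWeibull(tensile).fit(seed=0)


@pytest.fixture(scope="session")
def sw_fit_breaking(breaking):
    return SineWeibull(breaking).fit(seed=0)


@pytest.fixture
def unit_uniform():
    return make_baseline("uniform", 0.0, 1.0)
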