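import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from carotlab.dataio import load_bbd_fixture, read_factors_json, fixture_path
from carotlab.rsm import fit_quadratic


@pytest.fixture(scope="session")
def bbd_design_response():
    """The packaged 15-run design with its measured pigment yields."""
    return load_bbd_fixture()


@pytest.fixture(scope="session")
def bbd_fit(bbd_design_response):
    design, response = bbd_design_response
    return fit_quadratic(design, response)


@pytest.fixture(scope="session")
def study_factors():
    return read_factors_json(fixture_path("factors.json"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
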