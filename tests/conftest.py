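import numpy as np
import pytest

from carborne.response import (
    build_energy_bins,
    build_response_matrix,
    build_unit_flux_library,
)


@pytest.fixture(scope="session")
def bins():
    return build_energy_bins()


@pytest.fixture(scope="session")
def response(bins):
    return build_response_matrix(bins)


@pytest.fixture(scope="session")
def library(bins):
    # 3e5 histories per nuclide keeps Monte Carlo noise on the kerma
    # coefficients well below a percent while building in a few seconds
    return build_unit_flux_library(bins, histories=300_000, seed=20130923)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130923)
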