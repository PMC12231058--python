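import numpy as np
import pytest

from alpsim.io_formats import make_scheme, preset_scheme


@pytest.fixture(scope="session")
def hcp_scheme():
    """HCP-YA style scheme: b = 1000/2000/3000 x 90 directions + 18 b0."""
    return preset_scheme("hcp-ya")


@pytest.fixture(scope="session")
def small_scheme():
    """A cheap single-shell scheme for fit-heavy tests."""
    return make_scheme({1000.0: 30}, n_b0=3)


@pytest.fixture(scope="session")
def dispersion_context(hcp_scheme):
    from alpsim.dispersion_model import DispersionModelContext

    return DispersionModelContext(hcp_scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)
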