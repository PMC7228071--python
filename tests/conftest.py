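import numpy as np
import pytest

from burnhab.landscape import LandscapeParams, SelectionParams, generate_landscape, simulate_sites


@pytest.fixture(scope="session")
def small_landscape():
    """A 70x70 landscape shared by read-only tests."""
    return generate_landscape(LandscapeParams(shape=(70, 70), seed=11))


@pytest.fixture(scope="session")
def small_sites(small_landscape):
    sel = SelectionParams(n_nest=40, n_nonnest=120, n_available=2000, seed=12)
    return simulate_sites(small_landscape, sel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
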