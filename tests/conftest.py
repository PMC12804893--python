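import numpy as np
import pytest

from h2sink import RetentionCurve, SyntheticSpec, UptakeParams, gen_forcing


@pytest.fixture(scope="session")
def curve():
    return RetentionCurve(psi_e=-0.002, b=5.0)


@pytest.fixture(scope="session")
def params():
    return UptakeParams()


@pytest.fixture(scope="session")
def small_forcing():
    """A compact zone-structured grid for fast model tests."""
    spec = SyntheticSpec(seed=7, n_cells=30, n_times=400)
    return gen_forcing(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
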