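import numpy as np
import pytest

from fluocascade import fixtures
from fluocascade.spectral import SpectralGrid


@pytest.fixture(scope="session")
def grid():
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def fixture_spec():
    return fixtures.FixtureSpec()


@pytest.fixture(scope="session")
def dye(fixture_spec, grid):
    return fixtures.make_fluorophore(fixture_spec, grid)


@pytest.fixture(scope="session")
def source(fixture_spec, grid):
    return fixtures.make_source(fixture_spec, grid)


@pytest.fixture(scope="session")
def emission_truth(fixture_spec, grid):
    return fixtures.make_emission_truth(fixture_spec, grid)


@pytest.fixture(scope="session")
def overlap_slab(dye, grid):
    """Index-matched, non-scattering slab of dye: the analytic cascade fixture."""
    return fixtures.make_bare_slab([(dye, 1.0)], grid, thickness_mm=4.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
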