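import numpy as np
import pytest

from xtalcluster import FixtureSpec, generate_multidataset


@pytest.fixture(scope="session")
def small_fixture():
    """3 planted clusters x 6 data sets, ~150 reflections, 40 atoms."""
    spec = FixtureSpec(
        n_clusters=3, sizes=[6, 6, 6], n_reflections=150, n_atoms=40, seed=11
    )
    return generate_multidataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cubic_cell():
    return (100.0, 100.0, 100.0, 90.0, 90.0, 90.0)
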