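import numpy as np
import pytest

from ligoverlay import FixtureSpec, make_complex, make_fixture_set


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """A complete runnable example: card, reference, two entries, MTZ."""
    out = tmp_path_factory.mktemp("fixture_set")
    return make_fixture_set(out, seed=7)


@pytest.fixture(scope="session")
def base_complex():
    """Default P1 helix + ligand and its ligand selection."""
    return make_complex(FixtureSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
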