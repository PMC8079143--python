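import numpy as np
import pytest

from brainscene.atlas import load_atlas
from brainscene.synthetic import FixtureSpec, make_mini_atlas


@pytest.fixture(scope="session")
def atlas_dir(tmp_path_factory):
    """A synthetic mini-atlas bundle written once per test session."""
    d = tmp_path_factory.mktemp("bundle") / "mini_atlas"
    make_mini_atlas(FixtureSpec(), d)
    return d


@pytest.fixture(scope="session")
def atlas(atlas_dir):
    return load_atlas(atlas_dir)


@pytest.fixture(scope="session")
def toy_swc(tmp_path_factory):
    """The canonical 3-node morphology: soma with a 2-node dendrite."""
    p = tmp_path_factory.mktemp("swc") / "toy.swc"
    p.write_text(
        "# toy neuron\n"
        "1 1 0 0 0 5 -1\n"
        "2 3 10 0 0 1 1\n"
        "3 3 20 0 0 1 2\n"
    )
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
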