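import numpy as np
import pytest

from mbhis import FixtureSpec, generate_fixture, write_fixture_tree

# 32 px keeps the backbone forward passes cheap while preserving every
# dimension contract (GAP width is independent of spatial input size)
SMALL_SIZE = (32, 32)


@pytest.fixture(scope="session")
def fixture_set():
    """5-class synthetic texture set, 10 images per class, 32 px."""
    return generate_fixture(FixtureSpec(n_per_class=10, image_size=SMALL_SIZE, seed=1))


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """The same kind of set written as a folder-per-class PNG tree."""
    root = tmp_path_factory.mktemp("tree")
    data = generate_fixture(FixtureSpec(n_per_class=4, image_size=SMALL_SIZE, seed=5))
    write_fixture_tree(data, root)
    return root


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
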