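import numpy as np
import pytest

import phylogcn as pg


@pytest.fixture(scope="session")
def benchmark():
    """The default 2000-tip study fixture (seed 42), shared across tests."""
    return pg.generate_benchmark(seed=42)


@pytest.fixture(scope="session")
def small_tree():
    return pg.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
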