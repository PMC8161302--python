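import numpy as np
import pytest

from sharedrisk import AreaGraph, build_lattice


@pytest.fixture
def path3() -> AreaGraph:
    """Path graph A - B - C."""
    return AreaGraph(["A", "B", "C"], [(0, 1), (1, 2)])


@pytest.fixture
def lattice5() -> AreaGraph:
    return build_lattice(5, 5, "rook")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210526)
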