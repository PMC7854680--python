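import numpy as np
import pytest

from fignet.treecore import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar5():
    return parse_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


@pytest.fixture
def host8():
    return parse_newick(
        "((((A:1,B:1):1,C:2):1,(D:2,E:2):1):1,((F:2,G:2):1,H:3):1);"
    )
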