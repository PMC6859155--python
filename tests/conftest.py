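import numpy as np
import pytest

from peaknets import fixtures


@pytest.fixture(scope="session")
def demo22():
    """Read-only 22-nt demo network (5',5''-deuterated).  Tests that
    mutate network state must build their own."""
    return fixtures.demo_network_22()


@pytest.fixture()
def fresh22():
    return fixtures.demo_network_22()


@pytest.fixture(scope="session")
def net50():
    return fixtures.standard_rna_network(fixtures.HAIRPIN50_SEQ,
                                         fixtures.HAIRPIN50_DB)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
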