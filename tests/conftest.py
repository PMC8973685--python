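import numpy as np
import pytest

from spreadrank.generators import BAParams, barabasi_albert, fixture_graph
from spreadrank.graphio import Network


@pytest.fixture
def star4() -> Network:
    """Hub plus four leaves: every centrality has a closed form."""
    return fixture_graph("star", leaves=4)


@pytest.fixture
def k4() -> Network:
    return fixture_graph("complete", n=4)


@pytest.fixture
def p3() -> Network:
    return fixture_graph("path", n=3)


@pytest.fixture(scope="session")
def ba_small() -> Network:
    """A small preferential-attachment network shared across tests."""
    return barabasi_albert(BAParams(n_nodes=300, m=3, seed=42))


def random_graph(n: int, p: float, seed: int) -> Network:
    """Erdos-Renyi-style random simple graph used as an oracle substrate."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < p
    edges = np.column_stack([iu[0][mask], iu[1][mask]])
    return Network(n_nodes=n, edges=edges)
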