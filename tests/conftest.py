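import networkx as nx
import numpy as np
import pytest

from rsgnn.netio import Network


@pytest.fixture
def triangle():
    return Network.from_edges([(1, 2), (2, 3), (3, 1)])


@pytest.fixture
def path3():
    # a - b - c
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def path4():
    return Network.from_edges([(1, 2), (2, 3), (3, 4)])


@pytest.fixture
def star5():
    # hub 0, leaves 1..4
    return Network.from_edges([(0, i) for i in range(1, 5)])


@pytest.fixture
def k5():
    return Network.from_edges([(i, j) for i in range(5) for j in range(i + 1, 5)])


@pytest.fixture
def cycle6():
    return Network.from_edges([(i, (i + 1) % 6) for i in range(6)])


@pytest.fixture
def fig1_toy():
    """Worked 5-node example: edges 1-2, 1-3, 1-5, 2-3, 2-4, 3-4."""
    return Network.from_edges([(1, 2), (1, 3), (1, 5), (2, 3), (2, 4), (3, 4)])


def random_connected_graph(n, p, seed):
    """Erdos-Renyi G(n, p) conditioned on connectivity (resamples)."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(2**31)))
        if n == 1 or nx.is_connected(g):
            return Network.from_networkx(g)
    raise RuntimeError("could not sample a connected graph")


@pytest.fixture(scope="session")
def e2e_setup():
    """Transfer-protocol data at acceptance scale, shared across modules:
    BA(1000,4) + LFR(1000) training networks with threshold-rate SIR labels
    (Sn=100) and a held-out BA(500,4) test network."""
    from rsgnn.netio import generate_ba, generate_lfr
    from rsgnn.sir import SIRConfig, epidemic_threshold, label_all_nodes

    ba = generate_ba(1000, 4, seed=101)
    lfr = generate_lfr(1000, seed=102)
    test_g = generate_ba(500, 4, seed=103)
    lab_ba = label_all_nodes(
        ba, SIRConfig(beta=epidemic_threshold(ba), sn=100, rng_seed=201)
    )
    lab_lfr = label_all_nodes(
        lfr, SIRConfig(beta=epidemic_threshold(lfr), sn=100, rng_seed=202)
    )
    lab_test = label_all_nodes(
        test_g, SIRConfig(beta=epidemic_threshold(test_g), sn=100, rng_seed=203)
    )
    return (ba, lab_ba), (lfr, lab_lfr), test_g, lab_test


@pytest.fixture(scope="session")
def e2e_entropy_model(e2e_setup):
    """Entropy-variant model trained on the shared protocol data (seed 0)."""
    from rsgnn.rsgnn import TrainConfig, train

    (ba, lab_ba), (lfr, lab_lfr), _, _ = e2e_setup
    return train(
        TrainConfig(train_networks=[(ba, lab_ba), (lfr, lab_lfr)], rng_seed=0)
    )
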