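import numpy as np
import pytest

import oncosignal as osg
from oncosignal.io_formats import SignalingNetwork
from oncosignal.weights import WeightedStateNetwork


def make_weighted(edges, weights, state="test"):
    """Weighted network from (a, b) pairs and a pair->weight map."""
    net = SignalingNetwork.from_edges([(a, b, "undirected") for a, b in edges])
    pw = {tuple(sorted(p)): w for p, w in weights.items()}
    return WeightedStateNetwork(base=net, state=state, pair_weights=pw)


def random_weighted(rng, n_nodes=20, p=0.2, state="rand", typed=False, low=1.0, high=20.0):
    """Random connected typed weighted network for oracle comparisons."""
    names = [f"N{i:02d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):  # random tree keeps it connected
        j = int(rng.integers(0, i))
        edges.append((names[j], names[i]))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p and (names[i], names[j]) not in edges:
                edges.append((names[i], names[j]))
    kinds = ["activating", "inhibiting", "undirected"]
    typed_edges = []
    for a, b in edges:
        kind = kinds[int(rng.integers(0, 3))] if typed else "undirected"
        if kind in ("activating", "inhibiting") and rng.integers(0, 2):
            a, b = b, a
        typed_edges.append((a, b, kind))
    net = SignalingNetwork.from_edges(typed_edges)
    pw = {
        tuple(sorted((a, b))): float(rng.uniform(low, high))
        for a, b, _ in typed_edges
    }
    return WeightedStateNetwork(base=net, state=state, pair_weights=pw)


@pytest.fixture(scope="session")
def small_cfg():
    return osg.SyntheticConfig(
        n_nodes=60, n_edges=180, planted_module_size=10, n_samples=8, seed=11
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    net, matrices, gsc, truth = osg.simulate(small_cfg)
    return net, matrices, gsc, truth


@pytest.fixture(scope="session")
def small_states(small_sim):
    """Filtered network, abundance table and per-state weighted networks."""
    net, matrices, _, _ = small_sim
    table = osg.build_abundances({s: [m] for s, m in matrices.items()})
    filtered = osg.filter_network(net, set(table.genes))
    weighted = {
        s: osg.compute_link_weights(filtered, table.state(s), state=s)
        for s in table.states
    }
    return filtered, table, weighted
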