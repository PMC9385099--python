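import networkx as nx
import numpy as np
import pandas as pd
import pytest

from semgsa import ExpressionDataset, PathwayGraph


def make_pathway(name, edges, singletons=(), bidirected=()):
    """Build a PathwayGraph from (source, target, weight) triples."""
    g = nx.DiGraph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    g.add_nodes_from(singletons)
    return PathwayGraph(name, g, bidirected)


def make_noise_data(genes, n_cases=20, n_controls=20, seed=0):
    """Pure-noise expression dataset (standard normal, no group effect)."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    values = pd.DataFrame(
        rng.standard_normal((n, len(genes))),
        index=[f"s{i}" for i in range(n)],
        columns=list(genes),
    )
    group = np.array([1] * n_cases + [0] * n_controls)
    return ExpressionDataset(values, group)


@pytest.fixture
def chain_pathway():
    """A -> B -> C with activating edges."""
    return make_pathway("chain", [("A", "B", 1), ("B", "C", 1)])


@pytest.fixture
def random_pathway_factory():
    """Random DAG pathway with signed weights, for property-style loops."""

    def factory(n_nodes, seed, p_edge=0.15):
        rng = np.random.default_rng(seed)
        labels = [f"n{i:02d}" for i in range(n_nodes)]
        g = nx.DiGraph()
        g.add_nodes_from(labels)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < p_edge:
                    g.add_edge(
                        labels[i], labels[j], weight=int(rng.choice([-1, 0, 1]))
                    )
        return PathwayGraph(f"rand{seed}", g)

    return factory
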