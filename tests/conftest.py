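import numpy as np
import pytest

from calcinet import (
    CellTable,
    FunctionalGraph,
    SyntheticSpec,
    TraceMatrix,
    generate,
)
import networkx as nx


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic recording (60 cells, 3 assemblies, 450 frames
    at 0.5 Hz) with its ground truth."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture()
def toy_traces():
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(6, 40))
    return TraceMatrix(vals, [f"c{i}" for i in range(6)], 2.0)


def graph_from_edges(n_nodes, edges, labels=None):
    """Build a FunctionalGraph from an integer edge list (test helper)."""
    g = nx.Graph()
    for i in range(n_nodes):
        attrs = {}
        if labels is not None and labels[i] is not None:
            attrs["label"] = labels[i]
        g.add_node(str(i), **attrs)
    for u, v in edges:
        g.add_edge(str(u), str(v), weight=1.0)
    return FunctionalGraph(graph=g, theta=None)


@pytest.fixture()
def make_graph():
    return graph_from_edges
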