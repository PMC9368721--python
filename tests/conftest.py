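import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mediacite.network import CitationNetwork, MediaOutlet, UndirectedGraph


def make_outlet(node_id: str, country: str = "US") -> MediaOutlet:
    return MediaOutlet(
        id=node_id, name=f"Outlet {node_id}", country_code=country
    )


def make_network(edges, countries=None, stage="test") -> CitationNetwork:
    """Citation network from (source, target, weight) triples."""
    countries = countries or {}
    net = CitationNetwork(stage_label=stage)
    nodes = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    for node in sorted(nodes):
        net.add_outlet(make_outlet(node, countries.get(node, "US")))
    for u, v, w in edges:
        net.add_citation(u, v, w)
    return net


def random_undirected(n: int, p: float, seed: int) -> UndirectedGraph:
    rng = np.random.default_rng(seed)
    g = UndirectedGraph()
    names = [f"n{i:02d}" for i in range(n)]
    for name in names:
        g.add_node(name)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g


def random_citation_network(n: int, p: float, seed: int) -> CitationNetwork:
    """Random weighted digraph; guaranteed at least one edge."""
    rng = np.random.default_rng(seed)
    net = CitationNetwork(stage_label=f"rand{seed}")
    names = [f"n{i:02d}" for i in range(n)]
    for name in names:
        net.add_outlet(make_outlet(name))
    n_edges = 0
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                net.add_citation(names[i], names[j], int(rng.integers(1, 6)))
                n_edges += 1
    if n_edges == 0:
        net.add_citation(names[0], names[-1], 1)
    return net


@pytest.fixture
def two_triangles_bridge() -> UndirectedGraph:
    """Triangles {a,b,c} and {x,y,z} joined by the bridge c–x (7 edges)."""
    return UndirectedGraph.from_edges(
        [("a", "b"), ("a", "c"), ("b", "c"),
         ("x", "y"), ("x", "z"), ("y", "z"),
         ("c", "x")]
    )


@pytest.fixture
def triangle_pendant() -> UndirectedGraph:
    """Triangle {a,b,c} with pendant p attached to a."""
    return UndirectedGraph.from_edges(
        [("a", "b"), ("a", "c"), ("b", "c"), ("a", "p")]
    )
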