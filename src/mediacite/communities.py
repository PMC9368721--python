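"""Divisive community detection on peripheral components.

Classic Girvan–Newman: repeatedly recompute shortest-path edge betweenness
and remove the single highest-betweenness edge (lexicographic tie-break);
every removal that disconnects a component records the component partition
together with its modularity Q.  The best partition is the recorded one
with maximal Q, ties resolved toward fewer communities.

Q follows the standard endpoint formulation: for community i, e_ii is the
fraction of edges with both endpoints inside i and a_i the fraction of
edge endpoints inside i; Q = Σ_i (e_ii − a_i²).  A single community gives
exactly 0; a perfect split of disconnected cliques approaches 1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from .network import UndirectedGraph

__all__ = [
    "Partition",
    "Dendrogram",
    "edge_betweenness",
    "girvan_newman",
    "modularity",
    "best_partition",
]


@dataclass(frozen=True)
class Partition:
    """Disjoint communities covering a graph, with their modularity."""

    communities: Tuple[frozenset, ...]
    q: float

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def labels(self) -> Dict[str, int]:
        return {v: i for i, comm in enumerate(self.communities) for v in comm}


@dataclass(frozen=True)
class Dendrogram:
    """Ordered split log: (removed edge, partition recorded at that split)."""

    steps: Tuple[Tuple[Tuple[str, str], Partition], ...]


def edge_betweenness(
    graph: UndirectedGraph,
) -> Dict[Tuple[str, str], float]:
    """Shortest-path betweenness of every edge (Brandes accumulation).

    Value of edge e: over all unordered node pairs, the number of shortest
    paths through e, with credit split equally among equal-length shortest
    paths for the same pair.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph has no edge betweenness")
    bc: Dict[Tuple[str, str], float] = {e: 0.0 for e in graph.edges()}

    def ekey(u: str, v: str) -> Tuple[str, str]:
        return (u, v) if u < v else (v, u)

    for s in graph.nodes():
        # BFS computing shortest-path counts sigma and predecessor lists
        dist = {s: 0}
        sigma = {s: 1.0}
        preds: Dict[str, List[str]] = {s: []}
        order: List[str] = []
        frontier = [s]
        while frontier:
            nxt: List[str] = []
            for v in frontier:
                order.append(v)
                for w in graph.neighbors(v):
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        sigma[w] = 0.0
                        preds[w] = []
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            frontier = nxt
        # dependency accumulation, leaves first
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                credit = sigma[v] / sigma[w] * (1.0 + delta[w])
                bc[ekey(v, w)] += credit
                delta[v] += credit
    # every unordered pair was visited from both endpoints
    return {e: val / 2.0 for e, val in bc.items()}


def modularity(
    graph: UndirectedGraph, communities: Sequence[Set[str]]
) -> float:
    """Modularity Q of a partition on the graph's own edge set."""
    m = graph.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    label: Dict[str, int] = {}
    for i, comm in enumerate(communities):
        for v in comm:
            if v in label:
                raise ValueError(f"node {v!r} assigned to two communities")
            label[v] = i
    if set(label) != set(graph.nodes()):
        raise ValueError("communities must partition the node set")
    e_internal = [0.0] * len(communities)
    endpoints = [0.0] * len(communities)
    for u, v in graph.edges():
        if label[u] == label[v]:
            e_internal[label[u]] += 1.0
        endpoints[label[u]] += 1.0
        endpoints[label[v]] += 1.0
    q = 0.0
    for i in range(len(communities)):
        e_ii = e_internal[i] / m
        a_i = endpoints[i] / (2.0 * m)
        q += e_ii - a_i**2
    return q


def _component_partition(graph: UndirectedGraph) -> Tuple[frozenset, ...]:
    return tuple(frozenset(c) for c in graph.connected_components())


def girvan_newman(graph: UndirectedGraph) -> Dendrogram:
    """Full divisive dendrogram down to the edgeless graph.

    Betweenness is recomputed after every single removal; the maximal edge
    is removed, ties broken by lexicographic endpoint order.  A partition
    (with Q evaluated on the *original* graph) is recorded after each
    removal that raises the component count.
    """
    if graph.n_edges == 0:
        return Dendrogram(())
    work = graph.copy()
    steps: List[Tuple[Tuple[str, str], Partition]] = []
    n_comps = len(work.connected_components())
    while work.n_edges > 0:
        bc = edge_betweenness(work)
        # deterministic: highest betweenness, then lexicographically smallest
        best_val = max(bc.values())
        edge = min(e for e, val in bc.items() if val == best_val)
        work.remove_edge(*edge)
        comps = work.connected_components()
        if len(comps) > n_comps:
            n_comps = len(comps)
            communities = tuple(frozenset(c) for c in comps)
            q = modularity(graph, communities)
            steps.append((edge, Partition(communities, q)))
    return Dendrogram(tuple(steps))


def best_partition(graph: UndirectedGraph) -> Partition:
    """Dendrogram partition with maximal Q; ties go to fewer communities.

    The undivided partition (the graph's connected components, before any
    removal) competes as well, so a graph with no internal community
    structure comes back whole.
    """
    if graph.n_edges == 0:
        raise ValueError("best_partition requires at least one edge")
    initial_comms = _component_partition(graph)
    candidates = [Partition(initial_comms, modularity(graph, initial_comms))]
    candidates.extend(p for _, p in girvan_newman(graph).steps)
    return max(candidates, key=lambda p: (p.q, -p.n_communities))
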