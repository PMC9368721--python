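"""Independent brute-force oracles used to validate the graph algorithms.

These deliberately take the slow, obviously-correct route: explicit
shortest-path enumeration for betweenness, minimum-degree deletion for the
shell index, and a dense linear solve for the PageRank fixed point.  They
share no code with the implementations they check.
"""
from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Tuple

import numpy as np

from mediacite.network import CitationNetwork, UndirectedGraph


def brute_force_edge_betweenness(
    graph: UndirectedGraph,
) -> Dict[Tuple[str, str], float]:
    """Enumerate every shortest path for every pair; split credit equally."""
    bc: Dict[Tuple[str, str], float] = {
        tuple(sorted(e)): 0.0 for e in graph.edges()
    }
    nodes = sorted(graph.nodes())

    def all_shortest_paths(s: str, t: str) -> List[List[str]]:
        dist = graph.bfs_distances(s)
        if t not in dist:
            return []
        paths: List[List[str]] = []

        def extend(path: List[str]) -> None:
            head = path[-1]
            if head == t:
                paths.append(list(path))
                return
            for nbr in sorted(graph.neighbors(head)):
                if nbr in dist and dist[nbr] == dist[head] + 1 and (
                    t not in dist or dist[nbr] <= dist[t]
                ):
                    path.append(nbr)
                    extend(path)
                    path.pop()

        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    for s, t in combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        credit = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                bc[tuple(sorted((u, v)))] += credit
    return bc


def min_degree_deletion_shells(graph: UndirectedGraph) -> Dict[str, int]:
    """Shell index by repeatedly deleting a minimum-degree node.

    The classic sequential peeling: the running shell level k is the
    maximum minimum-degree seen so far (floored at 1, matching shells that
    start at layer 1).
    """
    work = graph.copy()
    shell: Dict[str, int] = {}
    k = 1
    while work.n_nodes > 0:
        v = min(work.nodes(), key=lambda u: (work.degree(u), u))
        k = max(k, work.degree(v))
        shell[v] = k
        work.remove_node(v)
    return shell


def pagerank_linear_solve(
    network: CitationNetwork, d: float
) -> Dict[str, float]:
    """Exact fixed point of the damped citation walk via a dense solve.

    p = (1-d)/N · 1 + d · Mᵀ p, where M is the row-stochastic transition
    matrix over outgoing citation weights and rows of outlets that cite
    nobody are uniform (dangling redistribution).
    """
    nodes = sorted(network.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for v in nodes:
        succ = network.successors(v)
        total = sum(succ.values())
        if total == 0:
            m[idx[v], :] = 1.0 / n
        else:
            for t, w in succ.items():
                m[idx[v], idx[t]] = w / total
    a = np.eye(n) - d * m.T
    b = np.full(n, (1.0 - d) / n)
    p = np.linalg.solve(a, b)
    return {v: float(p[idx[v]]) for v in nodes}
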