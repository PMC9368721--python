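"""k-shell decomposition and crust-component crossover core selection.

The network core is identified by iterative degree pruning (k-shell), then
choosing the threshold k* at which the k-crust's largest component jumps in
size while its second-largest component starts shrinking — the point where
the remaining deep shells carry the network's connectivity.  The core is
the k*-core; the periphery is the (k*−1)-crust.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import pandas as pd

from .errors import IngestError
from .network import CitationNetwork, UndirectedGraph

__all__ = [
    "ShellDecomposition",
    "CrustProfile",
    "CoreAssignment",
    "k_shell_decomposition",
    "crust_component_profile",
    "select_core_threshold",
    "assign_core",
    "core_coverage",
    "core_country_matrix",
]


@dataclass(frozen=True)
class ShellDecomposition:
    """Node → shell index from iterative pruning; shells start at 1."""

    shell: Dict[str, int]
    k_max: int

    def core_nodes(self, k: int) -> Set[str]:
        """The k-core: nodes with shell index >= k."""
        return {v for v, s in self.shell.items() if s >= k}

    def crust_nodes(self, k: int) -> Set[str]:
        """The k-crust: nodes with shell index <= k."""
        return {v for v, s in self.shell.items() if s <= k}


@dataclass(frozen=True)
class CrustProfile:
    """Per k: (largest, second-largest) component sizes of the k-crust."""

    sizes: Tuple[Tuple[int, int, int], ...]  # (k, largest, second_largest)


@dataclass(frozen=True)
class CoreAssignment:
    k_star: int
    core_nodes: frozenset
    periphery_nodes: frozenset
    coverage: float
    degenerate: bool = False


def k_shell_decomposition(
    graph: UndirectedGraph, use_strength: bool = False,
    weights: Dict[Tuple[str, str], int] | None = None,
) -> ShellDecomposition:
    """Iterative pruning: repeatedly strip all nodes of degree <= k.

    Starting at k = 1, every node whose current degree is at most k is
    removed (with its edges) and assigned shell k; when no such node
    remains, k increments.  The result is independent of removal order.

    With ``use_strength=True`` the pruning criterion is the weighted degree
    computed from ``weights`` (an alternative reading of degree-based
    pruning on weighted citation graphs); the default is plain degree.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph has no shell decomposition")

    def node_metric(g: UndirectedGraph, v: str) -> int:
        if not use_strength:
            return g.degree(v)
        assert weights is not None
        total = 0
        for nbr in g.neighbors(v):
            total += weights.get((v, nbr), 0) + weights.get((nbr, v), 0)
        return total

    if use_strength and weights is None:
        raise ValueError("use_strength requires an edge-weight mapping")

    work = graph.copy()
    shell: Dict[str, int] = {}
    k = 1
    while work.n_nodes > 0:
        stripped = True
        while stripped:
            to_remove = [v for v in work.nodes() if node_metric(work, v) <= k]
            stripped = bool(to_remove)
            for v in to_remove:
                shell[v] = k
                work.remove_node(v)
        if work.n_nodes > 0:
            k += 1
    return ShellDecomposition(shell=shell, k_max=max(shell.values()))


def crust_component_profile(
    graph: UndirectedGraph, shells: ShellDecomposition
) -> CrustProfile:
    """Component-size profile of the k-crust for k = 1..k_max."""
    rows: List[Tuple[int, int, int]] = []
    for k in range(1, shells.k_max + 1):
        crust = graph.subgraph(shells.crust_nodes(k))
        comps = crust.connected_components()
        largest = len(comps[0]) if comps else 0
        second = len(comps[1]) if len(comps) > 1 else 0
        rows.append((k, largest, second))
    return CrustProfile(tuple(rows))


def select_core_threshold(profile: CrustProfile) -> Tuple[int, bool]:
    """Crossover rule: pick k* where the largest crust component jumps.

    k* maximises Δ(k) = largest(k) − largest(k−1) among the k whose
    second-largest component did not grow (second(k) <= second(k−1));
    if no k qualifies, the unconstrained argmax of Δ is used.  Ties break
    toward the smallest k.  Returns (k_star, degenerate_flag); the flag is
    set when the profile holds a single k.
    """
    rows = profile.sizes
    if not rows:
        raise ValueError("empty crust profile")
    if len(rows) == 1:
        return rows[0][0], True
    largest = {k: lg for k, lg, _ in rows}
    second = {k: sc for k, _, sc in rows}
    ks = [k for k, _, _ in rows]
    prev = {ks[i]: ks[i - 1] if i > 0 else None for i in range(len(ks))}

    def delta(k: int) -> int:
        p = prev[k]
        return largest[k] - (largest[p] if p is not None else 0)

    eligible = [
        k for k in ks
        if prev[k] is not None and second[k] <= second[prev[k]]
    ]
    pool = eligible if eligible else ks
    best = max(pool, key=lambda k: (delta(k), -k))
    return best, False


def assign_core(
    graph: UndirectedGraph,
    shells: ShellDecomposition,
    network: CitationNetwork | None = None,
) -> CoreAssignment:
    """Run the crossover rule and split nodes into core and periphery.

    Core = k*-core (shell >= k*); periphery = (k*−1)-crust, so the two
    sets partition the nodes exactly.  Coverage (fraction of nodes in or
    adjacent to the core) is computed on ``network`` when given, else on
    the undirected graph.
    """
    profile = crust_component_profile(graph, shells)
    k_star, degenerate = select_core_threshold(profile)
    core = frozenset(shells.core_nodes(k_star))
    periphery = frozenset(shells.crust_nodes(k_star - 1))
    if network is not None:
        cov = core_coverage(network, core)
    else:
        cov = _coverage_undirected(graph, core)
    return CoreAssignment(k_star, core, periphery, cov, degenerate)


def _coverage_undirected(graph: UndirectedGraph, core: Iterable[str]) -> float:
    core_set = set(core)
    if not core_set or graph.n_nodes == 0:
        return 0.0
    touched = set(core_set)
    for v in core_set:
        touched |= graph.neighbors(v)
    return len(touched) / graph.n_nodes


def core_coverage(network: CitationNetwork, core: Iterable[str]) -> float:
    """Fraction of nodes in the core or sharing an edge (either direction)
    with a core node."""
    core_set = set(core)
    if not core_set:
        return 0.0
    touched = set(core_set)
    for v in core_set:
        touched |= set(network.successors(v))
        touched |= set(network.predecessors(v))
    return len(touched) / network.n_nodes


def core_country_matrix(
    network: CitationNetwork, core: Iterable[str]
) -> pd.DataFrame:
    """Cross-country citation matrix inside the core.

    Cell (r, c): total weight of core-internal edges from country r to
    country c, excluding domestic citations.  Rows and columns are ordered
    by descending total (row + column) citations so the heaviest flows sit
    in the upper-left corner.
    """
    core_set = set(core)
    for v in core_set:
        code = network.outlet(v).country_code
        if not code or code == "ZZ":
            raise IngestError(f"core outlet {v!r} lacks a country code")
    countries = sorted({network.outlet(v).country_code for v in core_set})
    mat = pd.DataFrame(0, index=countries, columns=countries, dtype=int)
    for u, v, w in network.edges():
        if u in core_set and v in core_set:
            r = network.outlet(u).country_code
            c = network.outlet(v).country_code
            if r != c:
                mat.loc[r, c] += w
    totals = mat.sum(axis=1) + mat.sum(axis=0)
    order = totals.sort_values(ascending=False, kind="stable").index
    return mat.loc[order, order]
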