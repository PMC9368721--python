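"""Core containers: media outlets, citation records, and the citation network.

A citation network is a simple directed graph whose nodes are media outlets
and whose positive integer edge weights count how many times the source
outlet cited the target outlet's reporting.  Self-loops are forbidden and
parallel records are merged by summing counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

from .errors import IngestError

__all__ = [
    "MediaOutlet",
    "CitationRecord",
    "CorpusSummary",
    "CitationNetwork",
    "UndirectedGraph",
]


@dataclass(frozen=True)
class MediaOutlet:
    """A media outlet: one node of the citation network.

    Parameters
    ----------
    id : str
        Unique opaque identifier.
    name : str
        Canonical outlet name as it appears in print.
    aliases : tuple of str
        Alternative names and abbreviations used when extracting citations
        from report text.
    country_code : str
        Two-letter uppercase country/region code (ISO 3166-1 alpha-2).
    region : str
        Continent label, used for regional aggregation.
    """

    id: str
    name: str
    aliases: Tuple[str, ...] = ()
    country_code: str = "ZZ"
    region: str = "Unknown"

    def __post_init__(self) -> None:
        if len(self.country_code) != 2 or not self.country_code.isupper():
            raise IngestError(
                f"outlet {self.id!r}: country_code must be two uppercase "
                f"letters, got {self.country_code!r}"
            )


@dataclass(frozen=True)
class CitationRecord:
    """One citing→cited relation with a multiplicity count."""

    citing_outlet: str
    cited_outlet: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise IngestError(f"citation count must be >= 1, got {self.count}")
        if self.citing_outlet == self.cited_outlet:
            raise IngestError(
                f"self-citation not allowed: {self.citing_outlet!r}"
            )


@dataclass(frozen=True)
class CorpusSummary:
    """Totals of a report corpus: the inputs to the damping-factor estimate."""

    n_reports: int
    n_citation_connections: int
    stage_label: str = ""

    def __post_init__(self) -> None:
        if self.n_citation_connections < 0:
            raise IngestError("n_citation_connections must be >= 0")


class CitationNetwork:
    """Simple directed graph with positive integer edge weights.

    Duplicate edges merge by summing weights; self-loops raise.  Nodes are
    registered :class:`MediaOutlet` objects; an edge endpoint must be a
    registered node.
    """

    def __init__(self, stage_label: str = ""):
        self.stage_label = stage_label
        self._outlets: Dict[str, MediaOutlet] = {}
        self._succ: Dict[str, Dict[str, int]] = {}
        self._pred: Dict[str, Dict[str, int]] = {}

    # -- construction -----------------------------------------------------

    def add_outlet(self, outlet: MediaOutlet) -> None:
        if outlet.id in self._outlets:
            return
        self._outlets[outlet.id] = outlet
        self._succ[outlet.id] = {}
        self._pred[outlet.id] = {}

    def add_citation(self, source: str, target: str, weight: int = 1) -> None:
        if source == target:
            raise IngestError(f"self-loop rejected: {source!r}")
        if weight < 1:
            raise IngestError(f"edge weight must be >= 1, got {weight}")
        for endpoint in (source, target):
            if endpoint not in self._outlets:
                raise IngestError(f"unregistered outlet in edge: {endpoint!r}")
        self._succ[source][target] = self._succ[source].get(target, 0) + weight
        self._pred[target][source] = self._pred[target].get(source, 0) + weight

    # -- inspection -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._outlets)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self._succ.values())

    @property
    def total_weight(self) -> int:
        return sum(w for t in self._succ.values() for w in t.values())

    def nodes(self) -> List[str]:
        return list(self._outlets)

    def outlet(self, node_id: str) -> MediaOutlet:
        return self._outlets[node_id]

    def outlets(self) -> List[MediaOutlet]:
        return list(self._outlets.values())

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._outlets

    def edges(self) -> Iterator[Tuple[str, str, int]]:
        for u, targets in self._succ.items():
            for v, w in targets.items():
                yield u, v, w

    def successors(self, node_id: str) -> Dict[str, int]:
        return dict(self._succ[node_id])

    def predecessors(self, node_id: str) -> Dict[str, int]:
        return dict(self._pred[node_id])

    def out_strength(self, node_id: str) -> int:
        """Total weight of outgoing citations (C_T in the influence model)."""
        return sum(self._succ[node_id].values())

    def in_strength(self, node_id: str) -> int:
        return sum(self._pred[node_id].values())

    def strength(self, node_id: str) -> int:
        """Citation-weighted total degree (in-strength + out-strength)."""
        return self.in_strength(node_id) + self.out_strength(node_id)

    # -- views ------------------------------------------------------------

    def undirected_view(self) -> "UndirectedGraph":
        """Simple undirected, unweighted view: {u,v} iff u→v or v→u."""
        g = UndirectedGraph()
        for node in self._outlets:
            g.add_node(node)
        for u, v, _ in self.edges():
            g.add_edge(u, v)
        return g

    def induced_subnetwork(self, keep: Iterable[str]) -> "CitationNetwork":
        keep_set = set(keep)
        sub = CitationNetwork(stage_label=self.stage_label)
        for node_id in keep_set:
            sub.add_outlet(self._outlets[node_id])
        for u, v, w in self.edges():
            if u in keep_set and v in keep_set:
                sub.add_citation(u, v, w)
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CitationNetwork):
            return NotImplemented
        return (
            self._outlets == other._outlets
            and self._succ == other._succ
        )


class UndirectedGraph:
    """Minimal simple undirected graph over hashable node ids."""

    def __init__(self) -> None:
        self._adj: Dict[str, Set[str]] = {}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        nodes: Optional[Iterable[str]] = None,
    ) -> "UndirectedGraph":
        g = cls()
        if nodes is not None:
            for n in nodes:
                g.add_node(n)
        for u, v in edges:
            g.add_edge(u, v)
        return g

    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, set())

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            return
        self.add_node(u)
        self.add_node(v)
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def remove_node(self, node: str) -> None:
        for nbr in self._adj.pop(node, set()):
            self._adj[nbr].discard(node)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def nodes(self) -> List[str]:
        return list(self._adj)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def neighbors(self, node: str) -> Set[str]:
        return self._adj[node]

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def edges(self) -> List[Tuple[str, str]]:
        """Distinct unordered pairs, each as a sorted tuple."""
        seen = []
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    seen.append((u, v))
        return seen

    def copy(self) -> "UndirectedGraph":
        g = UndirectedGraph()
        g._adj = {n: set(nbrs) for n, nbrs in self._adj.items()}
        return g

    def subgraph(self, keep: Iterable[str]) -> "UndirectedGraph":
        keep_set = set(keep)
        g = UndirectedGraph()
        for n in keep_set:
            if n in self._adj:
                g.add_node(n)
        for u, v in self.edges():
            if u in keep_set and v in keep_set:
                g.add_edge(u, v)
        return g

    def connected_components(self) -> List[Set[str]]:
        """Components sorted by size (desc), then by smallest member id."""
        seen: Set[str] = set()
        comps: List[Set[str]] = []
        for start in self._adj:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                node = stack.pop()
                for nbr in self._adj[node]:
                    if nbr not in comp:
                        comp.add(nbr)
                        stack.append(nbr)
            seen |= comp
            comps.append(comp)
        comps.sort(key=lambda c: (-len(c), min(c)))
        return comps

    def bfs_distances(self, source: str) -> Dict[str, int]:
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for node in frontier:
                for nbr in self._adj[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + 1
                        nxt.append(nbr)
            frontier = nxt
        return dist
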