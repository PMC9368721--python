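"""Whole-network structure: size/density metrics, scale-free fit, small world.

Topological statistics follow the convention of ignoring edge direction and
weights: degree distributions, clustering and path lengths are computed on
the simple undirected view.  The scale-free check is an ordinary
least-squares regression of the complementary cumulative degree
distribution F(n) = a·n^(−b) on log–log axes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .errors import DegenerateFitError
from .network import CitationNetwork, UndirectedGraph

__all__ = [
    "OverallMetrics",
    "DegreeDistribution",
    "PowerLawFit",
    "SmallWorldStats",
    "overall_metrics",
    "directed_density",
    "undirected_view",
    "complementary_cumulative_distribution",
    "fit_power_law",
    "small_world_stats",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at the given decimal precision.

    Report tables use this convention; internal computation never rounds.
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class OverallMetrics:
    """Size and connectivity summary of a directed citation network."""

    n_nodes: int
    n_edges: int
    total_weight: int
    density: float
    n_components: int
    largest_component_size: int
    density_defined: bool = True

    def as_row(self) -> Dict[str, object]:
        """One row in the printed summary-table layout."""
        return {
            "Number of Nodes": self.n_nodes,
            "Number of Edges": self.n_edges,
            "Total Edge Weights": self.total_weight,
            "Density": round_half_away(self.density, 3),
            "Number of Components": self.n_components,
            "Largest Component Size": self.largest_component_size,
        }


@dataclass(frozen=True)
class DegreeDistribution:
    """Complementary cumulative degree distribution.

    ``points`` maps each observed degree value n to F(n), the fraction of
    nodes with degree >= n.  F is non-increasing and equals 1 at the
    minimum observed degree.
    """

    points: Tuple[Tuple[int, float], ...]


@dataclass(frozen=True)
class PowerLawFit:
    """F(n) = a·n^(−b) fitted by OLS on log10 F vs log10 n."""

    a: float
    b: float
    r_squared: float


@dataclass(frozen=True)
class SmallWorldStats:
    characteristic_path_length: float
    average_local_clustering: float
    path_length_histogram: Dict[int, int]


def directed_density(n_nodes: int, n_edges: int) -> float:
    """Directed density E / (N·(N−1)); 0 when undefined (N <= 1)."""
    if n_nodes <= 1:
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1))


def overall_metrics(network: CitationNetwork) -> OverallMetrics:
    """Node/edge/weight counts, directed density, weak components."""
    n, e = network.n_nodes, network.n_edges
    comps = network.undirected_view().connected_components()
    return OverallMetrics(
        n_nodes=n,
        n_edges=e,
        total_weight=network.total_weight,
        density=directed_density(n, e),
        n_components=len(comps),
        largest_component_size=len(comps[0]) if comps else 0,
        density_defined=n > 1,
    )


def undirected_view(network: CitationNetwork) -> UndirectedGraph:
    """Simple undirected view: edge {u,v} iff u→v or v→u, weights dropped."""
    return network.undirected_view()


def complementary_cumulative_distribution(
    graph: UndirectedGraph,
) -> DegreeDistribution:
    if graph.n_nodes == 0:
        raise ValueError("empty graph has no degree distribution")
    degrees = sorted(graph.degree(v) for v in graph.nodes())
    n = len(degrees)
    points: List[Tuple[int, float]] = []
    arr = np.asarray(degrees)
    for value in sorted(set(degrees)):
        points.append((value, float((arr >= value).sum()) / n))
    return DegreeDistribution(tuple(points))


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """OLS of log10 F against log10 n; a = 10^intercept, b = −slope.

    Degrees of value 0 carry no information on log axes and are excluded;
    at least three distinct positive degree values are required.
    """
    pts = [(n, f) for n, f in dist.points if n > 0]
    if len(pts) < 3:
        raise DegenerateFitError(
            f"power-law fit needs >= 3 distinct positive degree values, "
            f"got {len(pts)}"
        )
    x = np.log10([n for n, _ in pts])
    y = np.log10([f for _, f in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(a=float(10.0**intercept), b=float(-slope), r_squared=r_squared)


def _local_clustering(graph: UndirectedGraph, node: str) -> float:
    nbrs = list(graph.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    nbr_set = graph.neighbors(node)
    # each edge between two neighbours is seen from both endpoints
    links = sum(len(graph.neighbors(u) & nbr_set) for u in nbrs) // 2
    return 2.0 * links / (k * (k - 1))


def small_world_stats(graph: UndirectedGraph) -> SmallWorldStats:
    """Characteristic path length, mean local clustering, distance histogram.

    Path length is the mean BFS distance over all unordered connected pairs
    inside the largest component; the clustering average runs over every
    node of the full graph, counting degree-<2 nodes as 0.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph has no small-world statistics")
    comps = graph.connected_components()
    largest = comps[0]
    sub = graph.subgraph(largest)
    histogram: Dict[int, int] = {}
    total = 0
    count = 0
    for source in sorted(largest):
        for target, d in sub.bfs_distances(source).items():
            if target <= source:
                continue
            histogram[d] = histogram.get(d, 0) + 1
            total += d
            count += 1
    cpl = total / count if count else 0.0
    clustering = sum(
        _local_clustering(graph, v) for v in graph.nodes()
    ) / graph.n_nodes
    return SmallWorldStats(
        characteristic_path_length=cpl,
        average_local_clustering=clustering,
        path_length_histogram=histogram,
    )
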