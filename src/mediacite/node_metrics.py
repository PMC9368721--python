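"""Outlet-level activity and influence scores.

Activity is the citation-weighted total degree (in + out strength)
normalised by N−1 so the two stage networks are comparable despite their
different sizes.  Influence is PageRank on the weighted citation graph
with an empirically estimated damping factor d: the probability that an
editor follows a citation chain rather than accessing the original
report, estimated as the proportion of reports that cite external
sources.  Each node receives (1−d)/N baseline mass plus d times the
citation-weighted share of its citers' mass; outlets citing nobody
redistribute their damped mass uniformly so no rank leaks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConvergenceError
from .network import CitationNetwork, CorpusSummary

__all__ = [
    "DampingEstimate",
    "NodeScores",
    "StageComparison",
    "normalized_degree",
    "estimate_damping_factor",
    "pagerank",
    "influence_share",
    "node_shares",
    "compare_stages",
]


@dataclass(frozen=True)
class DampingEstimate:
    """d = citation connections / reports, the empirical damping factor."""

    d: float
    numerator: int
    denominator: int
    clamped: bool = False


@dataclass(frozen=True)
class NodeScores:
    """Per-node score table for one stage network.

    Columns: country, strength, ndegree, pagerank, activity_share (sums to
    1), influence_share (percent, sums to 100).
    """

    table: pd.DataFrame
    stage_label: str = ""


@dataclass(frozen=True)
class StageComparison:
    """Share changes and size ratios between two stage networks."""

    outlets: pd.DataFrame
    countries: pd.DataFrame
    node_ratio: float
    edge_ratio: float
    core_node_ratio: Optional[float] = None
    core_edge_ratio: Optional[float] = None


def normalized_degree(network: CitationNetwork) -> Dict[str, float]:
    """Citation-weighted total degree over N−1, per node."""
    n = network.n_nodes
    if n < 2:
        raise ValueError("normalized degree needs at least two nodes")
    return {v: network.strength(v) / (n - 1) for v in network.nodes()}


def estimate_damping_factor(corpus: CorpusSummary) -> DampingEstimate:
    """Proportion of reports that cite an external source."""
    if corpus.n_reports <= 0:
        raise ValueError("corpus has no reports; d is undefined")
    raw = corpus.n_citation_connections / corpus.n_reports
    clamped = raw > 1.0
    return DampingEstimate(
        d=min(raw, 1.0),
        numerator=corpus.n_citation_connections,
        denominator=corpus.n_reports,
        clamped=clamped,
    )


def pagerank(
    network: CitationNetwork,
    d: float = 0.13,
    tolerance: float = 1e-9,
    max_iterations: int = 1000,
) -> Dict[str, float]:
    """Weighted PageRank by power iteration from the uniform vector.

    Each node keeps (1−d)/N baseline probability; with probability d, mass
    flows along outgoing citations in proportion to their weights.  Nodes
    with no outgoing citations spread their damped mass uniformly over all
    nodes.  Iteration stops when the L1 change drops below ``tolerance``;
    exceeding ``max_iterations`` raises :class:`ConvergenceError` carrying
    the last residual.

    For d = 1 (no teleport) the citation walk can be periodic and plain
    power iteration oscillates; the update is then averaged with the
    previous iterate, which preserves the fixed point and the total mass
    while restoring convergence.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"damping factor must lie in [0, 1], got {d}")
    nodes = sorted(network.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network has no PageRank")
    idx = {v: i for i, v in enumerate(nodes)}
    # sparse transition structure: for each node, (targets, weight shares)
    out: list[Optional[Tuple[np.ndarray, np.ndarray]]] = [None] * n
    for v in nodes:
        succ = network.successors(v)
        total = sum(succ.values())
        if total > 0:
            targets = np.array([idx[t] for t in succ], dtype=np.intp)
            shares = np.array([w / total for w in succ.values()], dtype=float)
            out[idx[v]] = (targets, shares)
    p = np.full(n, 1.0 / n)
    base = (1.0 - d) / n
    # at d = 1 the citation walk can be periodic; the lazy (averaged)
    # update has the same fixed point and restores convergence
    lazy = d >= 1.0
    for _ in range(max_iterations):
        new = np.full(n, base)
        dangling_mass = 0.0
        for i in range(n):
            if out[i] is None:
                dangling_mass += p[i]
            else:
                targets, shares = out[i]
                np.add.at(new, targets, d * p[i] * shares)
        new += d * dangling_mass / n
        if lazy:
            new = 0.5 * (new + p)
        residual = float(np.abs(new - p).sum())
        p = new
        if residual < tolerance:
            return {v: float(p[idx[v]]) for v in nodes}
    raise ConvergenceError(
        f"PageRank did not converge in {max_iterations} iterations "
        f"(last L1 residual {residual:.3e})",
        residual=residual,
    )


def influence_share(pagerank_value: float) -> float:
    """Influence as a percentage of network-wide influence.

    Network-total PageRank is 1, so a node's share is its PageRank × 100.
    """
    return pagerank_value * 100.0


def node_shares(
    network: CitationNetwork, pr: Dict[str, float], stage_label: str = ""
) -> NodeScores:
    """Assemble the per-node score table.

    activity_share = strength / (2 × total edge weight): each citation
    contributes one unit of activity at both endpoints, so shares sum to 1.
    influence_share = PageRank × 100 (percent).
    """
    total_weight = network.total_weight
    if total_weight == 0:
        raise ValueError("network has zero total weight")
    n = network.n_nodes
    ndeg = normalized_degree(network) if n >= 2 else {}
    rows = []
    for v in sorted(network.nodes()):
        strength = network.strength(v)
        rows.append(
            {
                "id": v,
                "country": network.outlet(v).country_code,
                "strength": strength,
                "ndegree": ndeg.get(v, 0.0),
                "pagerank": pr[v],
                "activity_share": strength / (2.0 * total_weight),
                "influence_share": influence_share(pr[v]),
            }
        )
    table = pd.DataFrame(rows).set_index("id")
    return NodeScores(table=table, stage_label=stage_label)


def _country_shares(scores: NodeScores) -> pd.DataFrame:
    g = scores.table.groupby("country")[["activity_share", "influence_share"]]
    return g.sum()


def compare_stages(
    scores1: NodeScores,
    scores2: NodeScores,
    net1: CitationNetwork,
    net2: CitationNetwork,
    cores: Optional[Tuple[Iterable[str], Iterable[str]]] = None,
) -> StageComparison:
    """Per-outlet and per-country share changes plus size ratios.

    Entities absent from a stage are reported with NaN shares for that
    stage (absent, not zero).  Ratios are stage2/stage1; when core node
    sets are given, core ratios use the induced core subnetworks.
    """
    t1 = scores1.table[["activity_share", "influence_share"]]
    t2 = scores2.table[["activity_share", "influence_share"]]
    outlets = t1.join(t2, how="outer", lsuffix="_s1", rsuffix="_s2")
    outlets["activity_change"] = (
        outlets["activity_share_s2"] - outlets["activity_share_s1"]
    )
    outlets["influence_change"] = (
        outlets["influence_share_s2"] - outlets["influence_share_s1"]
    )
    c1, c2 = _country_shares(scores1), _country_shares(scores2)
    countries = c1.join(c2, how="outer", lsuffix="_s1", rsuffix="_s2")
    countries["activity_change"] = (
        countries["activity_share_s2"] - countries["activity_share_s1"]
    )
    countries["influence_change"] = (
        countries["influence_share_s2"] - countries["influence_share_s1"]
    )
    core_node_ratio = core_edge_ratio = None
    if cores is not None:
        core1 = net1.induced_subnetwork(cores[0])
        core2 = net2.induced_subnetwork(cores[1])
        if core1.n_nodes > 0:
            core_node_ratio = core2.n_nodes / core1.n_nodes
        if core1.n_edges > 0:
            core_edge_ratio = core2.n_edges / core1.n_edges
    return StageComparison(
        outlets=outlets,
        countries=countries,
        node_ratio=net2.n_nodes / net1.n_nodes if net1.n_nodes else float("nan"),
        edge_ratio=net2.n_edges / net1.n_edges if net1.n_edges else float("nan"),
        core_node_ratio=core_node_ratio,
        core_edge_ratio=core_edge_ratio,
    )
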