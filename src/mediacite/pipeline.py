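"""End-to-end stage analysis: topology → core/periphery → communities → scores.

A stage report bundles, for one citation network, the overall metrics, the
power-law fit of the degree CCDF, small-world statistics, the shell
decomposition and crossover core assignment, peripheral community
partitions with their modularity, and the per-outlet score table.  Two
stage reports compare into a cross-stage report with share changes and
core size ratios.  Everything here is deterministic given its inputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import communities as comm
from . import core_periphery as cp
from . import node_metrics as nm
from . import topology as topo
from .errors import DegenerateFitError
from .network import CitationNetwork, CorpusSummary

__all__ = ["StageReport", "AnalysisReport", "run_stage", "run_comparison"]

SCHEMA_VERSION = 1

# peripheral components smaller than this are reported but not partitioned
MIN_COMMUNITY_COMPONENT = 4


@dataclass
class StageReport:
    stage_label: str
    metrics: topo.OverallMetrics
    power_law: Optional[topo.PowerLawFit]
    small_world: topo.SmallWorldStats
    shells: cp.ShellDecomposition
    crust_profile: cp.CrustProfile
    core: cp.CoreAssignment
    peripheral_partitions: List[comm.Partition]
    scores: nm.NodeScores
    damping: Optional[nm.DampingEstimate]
    input_checksums: Dict[str, str] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def summary_table_row(self) -> Dict[str, object]:
        return self.metrics.as_row()

    def to_dict(self) -> Dict[str, object]:
        """JSON-serialisable report body."""
        return {
            "schema_version": self.schema_version,
            "stage_label": self.stage_label,
            "input_checksums": self.input_checksums,
            "overall_metrics": self.metrics.as_row(),
            "power_law": (
                {
                    "a": self.power_law.a,
                    "b": self.power_law.b,
                    "r_squared": self.power_law.r_squared,
                }
                if self.power_law
                else "skipped: degenerate degree distribution"
            ),
            "small_world": {
                "characteristic_path_length": self.small_world.characteristic_path_length,
                "average_local_clustering": self.small_world.average_local_clustering,
                "path_length_histogram": {
                    str(k): v
                    for k, v in sorted(
                        self.small_world.path_length_histogram.items()
                    )
                },
            },
            "shells": {
                "k_max": self.shells.k_max,
                "n_layers": len(set(self.shells.shell.values())),
            },
            "core": {
                "k_star": self.core.k_star,
                "n_core_nodes": len(self.core.core_nodes),
                "n_periphery_nodes": len(self.core.periphery_nodes),
                "coverage": self.core.coverage,
            },
            "peripheral_partitions": [
                {
                    "n_communities": p.n_communities,
                    "q": p.q,
                    "sizes": sorted(
                        (len(c) for c in p.communities), reverse=True
                    ),
                }
                for p in self.peripheral_partitions
            ],
            "damping": (
                {
                    "d": self.damping.d,
                    "numerator": self.damping.numerator,
                    "denominator": self.damping.denominator,
                }
                if self.damping
                else "skipped: no corpus summary supplied"
            ),
            "top_influence": self.scores.table.sort_values(
                "pagerank", ascending=False
            )
            .head(10)[["pagerank", "influence_share"]]
            .round(6)
            .to_dict("index"),
        }


@dataclass
class AnalysisReport:
    stage1: StageReport
    stage2: StageReport
    comparison: nm.StageComparison
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> Dict[str, object]:
        return {
            "schema_version": self.schema_version,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "comparison": {
                "node_ratio": self.comparison.node_ratio,
                "edge_ratio": self.comparison.edge_ratio,
                "core_node_ratio": self.comparison.core_node_ratio,
                "core_edge_ratio": self.comparison.core_edge_ratio,
            },
        }


def checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def run_stage(
    network: CitationNetwork,
    corpus: Optional[CorpusSummary] = None,
    d: Optional[float] = None,
    input_checksums: Optional[Dict[str, str]] = None,
) -> StageReport:
    """Full single-stage analysis of one citation network.

    The damping factor used for PageRank is, in order of preference: the
    explicit ``d`` argument, the estimate from ``corpus``, or 0.13 (the
    corpus-level estimate for pandemic-alert news reporting).
    """
    if network.n_nodes == 0:
        raise ValueError("cannot analyse an empty network")
    metrics = topo.overall_metrics(network)
    graph = network.undirected_view()
    dist = topo.complementary_cumulative_distribution(graph)
    try:
        power_law = topo.fit_power_law(dist)
    except DegenerateFitError:
        power_law = None
    small_world = topo.small_world_stats(graph)
    shells = cp.k_shell_decomposition(graph)
    profile = cp.crust_component_profile(graph, shells)
    core = cp.assign_core(graph, shells, network=network)
    # communities are sought in the periphery; a degenerate split (every
    # node in the core) falls back to the full graph's components
    community_scope = core.periphery_nodes or frozenset(graph.nodes())
    periphery_graph = graph.subgraph(community_scope)
    partitions = []
    for component in periphery_graph.connected_components():
        if len(component) < MIN_COMMUNITY_COMPONENT:
            continue
        sub = periphery_graph.subgraph(component)
        if sub.n_edges == 0:
            continue
        partitions.append(comm.best_partition(sub))
    damping = nm.estimate_damping_factor(corpus) if corpus else None
    if d is None:
        d = damping.d if damping else 0.13
    pr = nm.pagerank(network, d=d)
    scores = nm.node_shares(network, pr, stage_label=network.stage_label)
    return StageReport(
        stage_label=network.stage_label,
        metrics=metrics,
        power_law=power_law,
        small_world=small_world,
        shells=shells,
        crust_profile=profile,
        core=core,
        peripheral_partitions=partitions,
        scores=scores,
        damping=damping,
        input_checksums=input_checksums or {},
    )


def run_comparison(
    report1: StageReport,
    report2: StageReport,
    net1: CitationNetwork,
    net2: CitationNetwork,
) -> AnalysisReport:
    """Merge two stage reports with the cross-stage comparison section."""
    if report1.schema_version != report2.schema_version:
        raise ValueError(
            "stage reports have mismatched schema versions: "
            f"{report1.schema_version} vs {report2.schema_version}"
        )
    comparison = nm.compare_stages(
        report1.scores,
        report2.scores,
        net1,
        net2,
        cores=(report1.core.core_nodes, report2.core.core_nodes),
    )
    return AnalysisReport(report1, report2, comparison)
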