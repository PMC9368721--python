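"""Synthetic media systems with planted core, communities, and report corpus.

The generator emulates the statistical structure of an international news
citation network during a health-emergency alert window: a heavy-tailed
(preferential-attachment) citation backbone, a dense deeply-nested core of
wire services and major outlets, country-affine peripheral communities,
and a report corpus in which a known fraction of reports cite an external
source (the ground-truth damping factor d).  Every quantity is driven by
one seeded generator, so identical configurations reproduce bit-identical
systems.

Default sizes mirror the first-stage study conditions at desk scale:
~400 outlets over 30 countries, mean directed degree ~3, mean citation
multiplicity ~3.25, d = 0.13.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from importlib import resources

from .errors import ConfigurationError, GenerationError
from .network import CitationNetwork, CitationRecord, CorpusSummary, MediaOutlet
from .ingest import continent_of

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_media_system",
    "generate_citation_network",
    "generate_report_corpus",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic media system.

    Parameters
    ----------
    n_outlets : int
        Number of media outlets.
    n_countries : int
        Number of countries outlets are spread over.
    country_size_skew : float
        Zipf-like exponent of the country-size distribution: country ranked
        r hosts outlets with probability ∝ r^(−skew).
    attachment_edges : int
        Edges added per new node in the preferential-attachment backbone
        (0 disables the backbone).
    triad_closure_prob : float
        Probability that a newcomer's follow-up attachment closes a
        triangle with a neighbour of its previous target instead of a
        fresh preferential pick; raises local clustering while keeping the
        degree tail of plain preferential attachment.
    within_country_affinity : float
        Probability of rewiring a backbone edge's target to a same-country
        outlet, producing domestic citation bias.
    planted_core_size : int
        Number of hub outlets densified into a deep k-shell core
        (0 disables the planted core).
    planted_communities : tuple of (size, p_internal, p_external)
        Peripheral blocks: within-block pair probability and cross-block
        pair probability.
    n_reports : int
        Reports in the synthetic corpus.
    citation_prob : float
        True probability that a report cites an external source (ground-
        truth damping factor d).
    weight_mean : float
        Mean citation multiplicity per edge (weights are 1 + a geometric
        variate with mean weight_mean − 1).
    seed : int
        Seed for the single global generator.
    """

    n_outlets: int = 400
    n_countries: int = 30
    country_size_skew: float = 1.2
    attachment_edges: int = 3
    triad_closure_prob: float = 0.6
    within_country_affinity: float = 0.3
    planted_core_size: int = 20
    planted_communities: Tuple[Tuple[int, float, float], ...] = (
        (8, 0.9, 0.02),
        (8, 0.9, 0.02),
        (8, 0.9, 0.02),
    )
    n_reports: int = 20000
    citation_prob: float = 0.13
    weight_mean: float = 3.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_outlets < 1:
            raise ConfigurationError("n_outlets must be >= 1")
        if not 1 <= self.n_countries <= self.n_outlets:
            raise ConfigurationError(
                "n_countries must lie in [1, n_outlets]"
            )
        if self.country_size_skew <= 0:
            raise ConfigurationError("country_size_skew must be positive")
        if self.attachment_edges < 0:
            raise ConfigurationError("attachment_edges must be >= 0")
        if not 0.0 <= self.triad_closure_prob <= 1.0:
            raise ConfigurationError("triad_closure_prob must lie in [0, 1]")
        if not 0.0 <= self.within_country_affinity <= 1.0:
            raise ConfigurationError(
                "within_country_affinity must lie in [0, 1]"
            )
        if not 0 <= self.planted_core_size <= self.n_outlets:
            raise ConfigurationError(
                "planted_core_size must lie in [0, n_outlets]"
            )
        for size, p_in, p_out in self.planted_communities:
            if size < 1:
                raise ConfigurationError("community size must be >= 1")
            if not 0.0 <= p_in <= 1.0 or not 0.0 <= p_out <= 1.0:
                raise ConfigurationError(
                    "community probabilities must lie in [0, 1]"
                )
        if sum(s for s, _, _ in self.planted_communities) > self.n_outlets:
            raise ConfigurationError(
                "community sizes must sum to <= n_outlets"
            )
        if self.n_reports < 0:
            raise ConfigurationError("n_reports must be >= 0")
        if not 0.0 <= self.citation_prob <= 1.0:
            raise ConfigurationError("citation_prob must lie in [0, 1]")
        if self.weight_mean < 1.0:
            raise ConfigurationError("weight_mean must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: community label and core flag per node, true d."""

    community_label: Dict[str, int]
    core_flag: Dict[str, bool]
    true_d: float

    @property
    def core_nodes(self) -> frozenset:
        return frozenset(v for v, f in self.core_flag.items() if f)


def _country_codes(n_countries: int) -> List[str]:
    with resources.files("mediacite.data").joinpath("countries.csv").open() as fh:
        codes = list(pd.read_csv(fh)["code"])
    if n_countries > len(codes):
        # extend with synthetic two-letter codes beyond the shipped table
        extra = (
            a + b
            for a in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
            for b in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        )
        for code in extra:
            if code not in codes:
                codes.append(code)
            if len(codes) >= n_countries:
                break
    return codes[:n_countries]


def generate_media_system(
    config: SyntheticConfig,
) -> Tuple[List[MediaOutlet], GroundTruth]:
    """Outlets with Zipf-skewed country labels, plus empty ground truth.

    Country ranked r receives outlets with probability ∝ r^(−skew);
    community labels and core flags are filled in by
    :func:`generate_citation_network`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _media_system(config, rng)


def _media_system(
    config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[List[MediaOutlet], GroundTruth]:
    codes = _country_codes(config.n_countries)
    ranks = np.arange(1, config.n_countries + 1, dtype=float)
    probs = ranks ** (-config.country_size_skew)
    probs /= probs.sum()
    assigned = rng.choice(config.n_countries, size=config.n_outlets, p=probs)
    width = len(str(config.n_outlets))
    outlets = []
    for i in range(config.n_outlets):
        code = codes[assigned[i]]
        outlets.append(
            MediaOutlet(
                id=f"outlet{i:0{width}d}",
                name=f"Outlet {i}",
                country_code=code,
                region=continent_of(code),
            )
        )
    truth = GroundTruth(
        community_label={o.id: -1 for o in outlets},
        core_flag={o.id: False for o in outlets},
        true_d=config.citation_prob,
    )
    return outlets, truth


def _preferential_attachment(
    n: int, m: int, rng: np.random.Generator, triad_prob: float = 0.0
) -> List[Tuple[int, int]]:
    """Preferential-attachment edge list over nodes 0..n−1.

    New nodes attach to m distinct existing nodes chosen proportionally to
    degree (repeated-endpoint urn).  With probability ``triad_prob`` a
    follow-up attachment instead closes a triangle with a neighbour of the
    node's previous target (triad-formation step), which raises clustering
    without changing the heavy degree tail.  Edges are oriented new→old:
    a newcomer outlet cites established ones.
    """
    if m < 1 or n <= m:
        return []
    edges: List[Tuple[int, int]] = []
    urn: List[int] = list(range(m))  # seed nodes, degree-0 start
    nbrs: Dict[int, List[int]] = {i: [] for i in range(n)}
    for new in range(m, n):
        targets: set = set()
        prev: Optional[int] = None
        while len(targets) < m:
            pick: Optional[int] = None
            if (
                prev is not None
                and triad_prob > 0
                and rng.random() < triad_prob
            ):
                candidates = [
                    c for c in nbrs[prev] if c != new and c not in targets
                ]
                if candidates:
                    pick = int(candidates[rng.integers(len(candidates))])
            if pick is None:
                pick = int(urn[rng.integers(len(urn))]) if urn else int(
                    rng.integers(new)
                )
                if pick == new or pick in targets:
                    continue
            targets.add(pick)
            prev = pick
        for t in sorted(targets):
            edges.append((new, t))
            urn.append(new)
            urn.append(t)
            nbrs[new].append(t)
            nbrs[t].append(new)
    return edges


def generate_citation_network(
    config: SyntheticConfig,
) -> Tuple[CitationNetwork, GroundTruth]:
    """Directed weighted citation network with planted structure.

    Construction order: preferential-attachment backbone (oriented
    newcomer→incumbent), country-affine target rewiring, core
    densification among the highest-degree nodes, then planted community
    blocks over otherwise-unused outlets.  Weights are 1 + geometric
    multiplicities around ``weight_mean``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outlets, truth = _media_system(config, rng)
    n = config.n_outlets
    ids = [o.id for o in outlets]
    country = {o.id: o.country_code for o in outlets}
    by_country: Dict[str, List[int]] = {}
    for i, o in enumerate(outlets):
        by_country.setdefault(o.country_code, []).append(i)

    directed: set = set()  # (src_index, dst_index)

    def undirected_present(u: int, v: int) -> bool:
        return (u, v) in directed or (v, u) in directed

    # --- backbone ---------------------------------------------------------
    m = config.attachment_edges
    backbone = (
        _preferential_attachment(n, m, rng, config.triad_closure_prob)
        if m > 0
        else []
    )
    for u, v in backbone:
        # country-affine rewiring of the cited endpoint
        if (
            config.within_country_affinity > 0
            and rng.random() < config.within_country_affinity
        ):
            peers = by_country[country[ids[u]]]
            if len(peers) > 1:
                candidate = int(peers[rng.integers(len(peers))])
                if candidate != u and not undirected_present(u, candidate):
                    v = candidate
        if u != v and not undirected_present(u, v):
            directed.add((u, v))

    # --- core densification ----------------------------------------------
    degree = np.zeros(n, dtype=int)
    for u, v in directed:
        degree[u] += 1
        degree[v] += 1
    core_size = config.planted_core_size
    core_indices: List[int] = []
    if core_size > 0:
        order = np.argsort(-degree, kind="stable")
        core_indices = [int(i) for i in order[:core_size]]
        target = max(2, int(np.ceil(0.6 * (core_size - 1))))
        if target > core_size - 1:
            raise GenerationError(
                "planted core too small to densify to the target degree"
            )
        internal = {
            i: sum(
                1
                for j in core_indices
                if j != i and undirected_present(i, j)
            )
            for i in core_indices
        }
        core_arr = np.array(core_indices)
        for i in core_indices:
            attempts = 0
            while internal[i] < target and attempts < 20 * core_size:
                j = int(core_arr[rng.integers(core_size)])
                attempts += 1
                if j == i or undirected_present(i, j):
                    continue
                src, dst = (i, j) if rng.random() < 0.5 else (j, i)
                directed.add((src, dst))
                internal[i] += 1
                internal[j] += 1
        for i in core_indices:
            truth.core_flag[ids[i]] = True

    # --- planted communities ---------------------------------------------
    used = set(core_indices)
    backbone_touched = {u for u, _ in directed} | {v for _, v in directed}
    free = [i for i in range(n) if i not in used]
    # prefer outlets untouched by the backbone so blocks stay peripheral
    free.sort(key=lambda i: (i in backbone_touched, i))
    blocks: List[List[int]] = []
    cursor = 0
    for size, p_in, p_out in config.planted_communities:
        if cursor + size > len(free):
            raise GenerationError(
                "not enough outlets left to plant the requested communities"
            )
        block = free[cursor : cursor + size]
        cursor += size
        blocks.append(block)
    for b, (block, (size, p_in, p_out)) in enumerate(
        zip(blocks, config.planted_communities)
    ):
        for label_node in block:
            truth.community_label[ids[label_node]] = b
        for ii in range(size):
            for jj in range(ii + 1, size):
                if rng.random() < p_in:
                    u, v = block[ii], block[jj]
                    if not undirected_present(u, v):
                        src, dst = (u, v) if rng.random() < 0.5 else (v, u)
                        directed.add((src, dst))
    # cross-block edges at the mean external probability of the pair
    for b1 in range(len(blocks)):
        for b2 in range(b1 + 1, len(blocks)):
            p_out = 0.5 * (
                config.planted_communities[b1][2]
                + config.planted_communities[b2][2]
            )
            if p_out <= 0:
                continue
            for u in blocks[b1]:
                for v in blocks[b2]:
                    if rng.random() < p_out and not undirected_present(u, v):
                        src, dst = (u, v) if rng.random() < 0.5 else (v, u)
                        directed.add((src, dst))

    # --- weights and assembly --------------------------------------------
    net = CitationNetwork(stage_label=f"synthetic-seed{config.seed}")
    touched = {u for u, _ in directed} | {v for _, v in directed}
    for i in sorted(touched):
        net.add_outlet(outlets[i])
    extra_mean = config.weight_mean - 1.0
    for u, v in sorted(directed):
        if extra_mean > 0:
            weight = 1 + int(rng.geometric(1.0 / (extra_mean + 1.0))) - 1
        else:
            weight = 1
        net.add_citation(ids[u], ids[v], max(1, weight))
    return net, truth


def generate_report_corpus(
    config: SyntheticConfig, network: CitationNetwork
) -> Tuple[CorpusSummary, List[CitationRecord]]:
    """Report corpus over the network's outlets.

    Each of ``n_reports`` reports is published by a uniformly drawn outlet
    and, with probability ``citation_prob``, cites one external outlet
    (following one of the publisher's outgoing citation edges when it has
    any, otherwise a uniformly drawn distinct outlet).  The summary totals
    are consistent with the returned record list by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    nodes = sorted(network.nodes())
    if not nodes:
        raise GenerationError("cannot write a corpus over an empty network")
    records: List[CitationRecord] = []
    cites = rng.random(config.n_reports) < config.citation_prob
    publishers = rng.integers(len(nodes), size=config.n_reports)
    for r in range(config.n_reports):
        if not cites[r]:
            continue
        publisher = nodes[publishers[r]]
        succ = sorted(network.successors(publisher))
        if succ and len(nodes) > 1:
            cited = succ[rng.integers(len(succ))]
        elif len(nodes) > 1:
            while True:
                cited = nodes[rng.integers(len(nodes))]
                if cited != publisher:
                    break
        else:
            continue
        records.append(CitationRecord(publisher, cited, 1))
    summary = CorpusSummary(
        n_reports=config.n_reports,
        n_citation_connections=len(records),
        stage_label=network.stage_label,
    )
    return summary, records
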