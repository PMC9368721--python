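"""Build validated citation networks from citation records or raw reports.

The ingest layer mirrors how a news-citation corpus is turned into a graph:
report snippets are scanned against an outlet-name thesaurus (case
insensitive, longest alias first), each detected mention becomes one
citing→cited record, duplicate records merge by summing counts, and outlets
that neither cite nor are cited stay out of the network.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .errors import IngestError
from .network import CitationNetwork, CitationRecord, MediaOutlet

__all__ = [
    "ReportRecord",
    "ExtractionResult",
    "continent_of",
    "extract_citations",
    "build_network",
    "aggregate_by_country",
    "review_error_rate",
]


@dataclass(frozen=True)
class ReportRecord:
    """A raw news report: id, publishing outlet id, and a text snippet."""

    report_id: str
    outlet_id: str
    text: str


@dataclass
class ExtractionResult:
    """Citation records extracted from a report batch.

    ``n_skipped_reports`` counts reports whose publishing outlet was absent
    from the thesaurus (skipped with a warning rather than failing the run).
    """

    records: List[CitationRecord]
    n_reports: int
    n_skipped_reports: int = 0


_CONTINENTS: Optional[Dict[str, str]] = None


def continent_of(country_code: str) -> str:
    """Continent label for a two-letter country code (``Unknown`` if absent)."""
    global _CONTINENTS
    if _CONTINENTS is None:
        with resources.files("mediacite.data").joinpath("countries.csv").open() as fh:
            table = pd.read_csv(fh)
        _CONTINENTS = dict(zip(table["code"], table["continent"]))
    return _CONTINENTS.get(country_code.upper(), "Unknown")


def _alias_index(thesaurus: Sequence[MediaOutlet]) -> List[Tuple[str, str]]:
    """(alias_lower, outlet_id) pairs, longest alias first."""
    pairs: List[Tuple[str, str]] = []
    for outlet in thesaurus:
        names = (outlet.name, *outlet.aliases)
        for name in names:
            name = name.strip()
            if not name:
                raise IngestError(
                    f"outlet {outlet.id!r} has an empty name/alias"
                )
            pairs.append((name.lower(), outlet.id))
    # longest first so "The Washington Post" wins over a nested "Post"
    pairs.sort(key=lambda p: (-len(p[0]), p[0], p[1]))
    return pairs


def extract_citations(
    reports: Iterable[ReportRecord],
    thesaurus: Sequence[MediaOutlet],
) -> ExtractionResult:
    """Detect outlet-name mentions in report snippets.

    Each mention of a thesaurus name or alias yields one record directed
    from the publishing outlet to the mentioned outlet.  Matching is case
    insensitive and longest-alias-first: a span claimed by a longer alias is
    not re-matched by a shorter one.  Self-mentions are dropped.  The result
    is invariant to report order (records are emitted per report and carry
    no cross-report state).
    """
    index = _alias_index(thesaurus)
    known_ids = {o.id for o in thesaurus}
    patterns = [
        (re.compile(r"(?<!\w)" + re.escape(alias) + r"(?!\w)", re.IGNORECASE), oid)
        for alias, oid in index
    ]
    records: List[CitationRecord] = []
    n_reports = 0
    n_skipped = 0
    for report in reports:
        n_reports += 1
        if report.outlet_id not in known_ids:
            n_skipped += 1
            continue
        claimed: List[Tuple[int, int]] = []
        mentions: List[Tuple[int, str]] = []
        for pattern, oid in patterns:
            for m in pattern.finditer(report.text):
                span = (m.start(), m.end())
                if any(s < span[1] and span[0] < e for s, e in claimed):
                    continue
                claimed.append(span)
                mentions.append((m.start(), oid))
        mentions.sort()
        for _, cited in mentions:
            if cited == report.outlet_id:
                continue
            records.append(CitationRecord(report.outlet_id, cited, 1))
    return ExtractionResult(records, n_reports, n_skipped)


def build_network(
    records: Iterable[CitationRecord],
    outlets: Sequence[MediaOutlet],
    stage_label: str = "",
) -> CitationNetwork:
    """Assemble a citation network from records.

    Duplicate (source, target) pairs merge by summing counts; outlets that
    appear in no record are excluded (isolates never enter the network).
    """
    by_id = {o.id: o for o in outlets}
    merged: Dict[Tuple[str, str], int] = {}
    for rec in records:
        for endpoint in (rec.citing_outlet, rec.cited_outlet):
            if endpoint not in by_id:
                raise IngestError(
                    f"record ({rec.citing_outlet!r} -> {rec.cited_outlet!r}):"
                    f" unknown outlet {endpoint!r}"
                )
        key = (rec.citing_outlet, rec.cited_outlet)
        merged[key] = merged.get(key, 0) + rec.count
    net = CitationNetwork(stage_label=stage_label)
    touched = {u for u, _ in merged} | {v for _, v in merged}
    for node_id in touched:
        net.add_outlet(by_id[node_id])
    for (u, v), w in merged.items():
        net.add_citation(u, v, w)
    return net


def aggregate_by_country(network: CitationNetwork) -> pd.DataFrame:
    """Country-level citation matrix.

    Cell (r, c) is the total weight of edges from country-r outlets to
    country-c outlets; the diagonal holds domestic citations.  Total matrix
    weight equals the network's total edge weight (conservation).
    """
    countries = sorted(
        {network.outlet(n).country_code for n in network.nodes()}
    )
    for node_id in network.nodes():
        code = network.outlet(node_id).country_code
        if not code or code == "ZZ":
            raise IngestError(f"outlet {node_id!r} lacks a country code")
    mat = pd.DataFrame(0, index=countries, columns=countries, dtype=int)
    for u, v, w in network.edges():
        r = network.outlet(u).country_code
        c = network.outlet(v).country_code
        mat.loc[r, c] += w
    return mat


def review_error_rate(n_invalid: int, n_sampled: int) -> float:
    """Manual-review error rate, as a percentage of the sampled reports."""
    if n_sampled <= 0:
        raise IngestError("n_sampled must be positive")
    if not 0 <= n_invalid <= n_sampled:
        raise IngestError("n_invalid must lie in [0, n_sampled]")
    return 100.0 * n_invalid / n_sampled
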