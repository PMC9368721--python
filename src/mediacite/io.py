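"""Delimited-table and GraphML readers/writers for citation networks.

Formats:
- edge list CSV with header ``source,target,weight``
- node table CSV with header ``id,name,country,region``
- thesaurus CSV with header ``id,name,alias`` (one alias per row; rows may
  repeat an id to add aliases)
- GraphML with ``weight`` edge attribute and ``name``/``country``/``region``
  node attributes
- ground-truth node table CSV ``id,community,core``
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, IngestError
from .network import CitationNetwork, MediaOutlet
from .synthetic import GroundTruth, SyntheticConfig

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_node_table",
    "read_node_table",
    "write_graphml",
    "read_graphml",
    "read_thesaurus",
    "write_ground_truth",
    "load_config",
]

PathLike = Union[str, Path]


def write_edge_list(network: CitationNetwork, path: PathLike) -> None:
    rows = sorted(network.edges())
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def write_node_table(network: CitationNetwork, path: PathLike) -> None:
    rows = [
        (o.id, o.name, o.country_code, o.region)
        for o in sorted(network.outlets(), key=lambda o: o.id)
    ]
    pd.DataFrame(rows, columns=["id", "name", "country", "region"]).to_csv(
        path, index=False
    )


def read_node_table(path: PathLike) -> List[MediaOutlet]:
    table = pd.read_csv(path, dtype=str)
    required = {"id", "name", "country", "region"}
    if not required.issubset(table.columns):
        raise IngestError(
            f"node table {path} must have columns {sorted(required)}"
        )
    return [
        MediaOutlet(
            id=row.id, name=row.name,
            country_code=row.country, region=row.region,
        )
        for row in table.itertuples(index=False)
    ]


def read_edge_list(
    path: PathLike,
    outlets: Sequence[MediaOutlet],
    stage_label: str = "",
) -> CitationNetwork:
    table = pd.read_csv(path)
    required = {"source", "target", "weight"}
    if not required.issubset(table.columns):
        raise IngestError(
            f"edge list {path} must have columns {sorted(required)}"
        )
    by_id = {o.id: o for o in outlets}
    net = CitationNetwork(stage_label=stage_label)
    for row in table.itertuples(index=False):
        for endpoint in (row.source, row.target):
            if endpoint not in by_id:
                raise IngestError(f"edge endpoint {endpoint!r} not in node table")
            net.add_outlet(by_id[endpoint])
        net.add_citation(row.source, row.target, int(row.weight))
    return net


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(network: CitationNetwork, path: PathLike) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    keys = [
        ("d_name", "node", "name"),
        ("d_country", "node", "country"),
        ("d_region", "node", "region"),
        ("d_weight", "edge", "weight"),
    ]
    for key_id, domain, name in keys:
        ET.SubElement(
            root,
            f"{{{_GRAPHML_NS}}}key",
            id=key_id,
            attrib={
                "for": domain,
                "attr.name": name,
                "attr.type": "long" if name == "weight" else "string",
            },
        )
    graph = ET.SubElement(
        root, f"{{{_GRAPHML_NS}}}graph",
        id=network.stage_label or "G", edgedefault="directed",
    )
    for outlet in sorted(network.outlets(), key=lambda o: o.id):
        node = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=outlet.id)
        for key_id, value in (
            ("d_name", outlet.name),
            ("d_country", outlet.country_code),
            ("d_region", outlet.region),
        ):
            data = ET.SubElement(node, f"{{{_GRAPHML_NS}}}data", key=key_id)
            data.text = value
    for u, v, w in sorted(network.edges()):
        edge = ET.SubElement(
            graph, f"{{{_GRAPHML_NS}}}edge", source=u, target=v
        )
        data = ET.SubElement(edge, f"{{{_GRAPHML_NS}}}data", key="d_weight")
        data.text = str(w)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_graphml(path: PathLike, stage_label: str = "") -> CitationNetwork:
    tree = ET.parse(path)
    root = tree.getroot()
    key_names = {
        el.get("id"): el.get("attr.name")
        for el in root.findall(f"{{{_GRAPHML_NS}}}key")
    }
    graph = root.find(f"{{{_GRAPHML_NS}}}graph")
    if graph is None:
        raise IngestError(f"{path}: no <graph> element")
    net = CitationNetwork(stage_label=stage_label or graph.get("id", ""))
    for node in graph.findall(f"{{{_GRAPHML_NS}}}node"):
        attrs = {
            key_names.get(d.get("key"), d.get("key")): d.text or ""
            for d in node.findall(f"{{{_GRAPHML_NS}}}data")
        }
        net.add_outlet(
            MediaOutlet(
                id=node.get("id"),
                name=attrs.get("name", node.get("id")),
                country_code=attrs.get("country", "ZZ"),
                region=attrs.get("region", "Unknown"),
            )
        )
    for edge in graph.findall(f"{{{_GRAPHML_NS}}}edge"):
        attrs = {
            key_names.get(d.get("key"), d.get("key")): d.text
            for d in edge.findall(f"{{{_GRAPHML_NS}}}data")
        }
        net.add_citation(
            edge.get("source"), edge.get("target"),
            int(attrs.get("weight", 1)),
        )
    return net


def read_thesaurus(path: PathLike) -> List[MediaOutlet]:
    """Thesaurus CSV ``id,name,alias``; repeated ids accumulate aliases."""
    table = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "name", "alias"}
    if not required.issubset(table.columns):
        raise IngestError(
            f"thesaurus {path} must have columns {sorted(required)}"
        )
    names: Dict[str, str] = {}
    aliases: Dict[str, List[str]] = {}
    for row in table.itertuples(index=False):
        names.setdefault(row.id, row.name)
        if row.alias:
            aliases.setdefault(row.id, []).append(row.alias)
    return [
        MediaOutlet(id=i, name=names[i], aliases=tuple(aliases.get(i, ())))
        for i in names
    ]


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    rows = [
        (v, truth.community_label[v], int(truth.core_flag[v]))
        for v in sorted(truth.community_label)
    ]
    pd.DataFrame(rows, columns=["id", "community", "core"]).to_csv(
        path, index=False
    )


def load_config(path: PathLike) -> SyntheticConfig:
    """Synthetic-system configuration from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    if "planted_communities" in raw:
        raw["planted_communities"] = tuple(
            (int(s), float(pi), float(po))
            for s, pi, po in raw["planted_communities"]
        )
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(
            f"unknown configuration fields: {sorted(unknown)}"
        )
    config = SyntheticConfig(**raw)
    config.validate()
    return config
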