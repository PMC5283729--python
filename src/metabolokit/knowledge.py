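"""Flat-file property-graph store and biological network queries.

A knowledge graph of typed molecular entities (gene, protein, compound,
microRNA, pathway) and typed relations is loaded from node/edge TSV
files, schema-validated, and queried for simple (single-relation) or
heterogeneous (multi-relation) neighbourhood networks around seed
entities — e.g. a gene linked to the compounds its enzyme product acts
on, via CONVERSION then CATALYSIS edges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .networks import WeightedNetwork

__all__ = [
    "NODE_TYPES",
    "RELATION_SCHEMA",
    "KnowledgeGraph",
    "load_graph",
    "write_graph",
    "query_simple_network",
    "query_heterogeneous_network",
    "annotation_sets_from_graph",
    "map_identifiers",
]

NODE_TYPES = ("gene", "protein", "compound", "microRNA", "pathway")

#: allowed (source type, target type) pairs per relation
RELATION_SCHEMA: dict[str, set[tuple[str, str]]] = {
    "BIOCHEMICAL_REACTION": {("compound", "compound")},
    "CATALYSIS": {("protein", "compound")},
    "MOLECULAR_BINDING": {("protein", "protein")},
    "CONVERSION": {("gene", "protein")},
    "CONTROL": {("protein", "gene"), ("microRNA", "gene")},
    "GENETIC_ASSOCIATION": {("gene", "gene")},
    "ANNOTATION": {("pathway", t) for t in ("gene", "protein", "compound", "microRNA")},
}


class SchemaError(ValueError):
    pass


@dataclass
class KnowledgeGraph:
    """Typed directed multigraph over molecular entities."""

    graph: nx.MultiDiGraph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["node_type"]

    def edges(self) -> list[tuple[str, str, str]]:
        return [(u, v, d["relation_type"]) for u, v, d in self.graph.edges(data=True)]


def _validate(g: nx.MultiDiGraph) -> None:
    for node, data in g.nodes(data=True):
        t = data.get("node_type")
        if t not in NODE_TYPES:
            raise SchemaError(f"node {node!r} has unknown type {t!r}")
    bad = []
    for u, v, d in g.edges(data=True):
        rel = d.get("relation_type")
        if rel not in RELATION_SCHEMA:
            raise SchemaError(f"unknown relation {rel!r} on edge {u!r}->{v!r}")
        pair = (g.nodes[u]["node_type"], g.nodes[v]["node_type"])
        if pair not in RELATION_SCHEMA[rel]:
            bad.append((u, v, rel, pair))
    if bad:
        msgs = "; ".join(f"{u}->{v} [{rel}] has types {pair}" for u, v, rel, pair in bad)
        raise SchemaError(f"relation/type schema violation(s): {msgs}")


def build_graph(nodes: pd.DataFrame, edges: pd.DataFrame) -> KnowledgeGraph:
    """Assemble and validate a KnowledgeGraph from node and edge tables.

    ``nodes`` needs columns (id, node_type[, name]); ``edges`` needs
    (source, target, relation_type[, attributes]) where attributes is a
    JSON object column.
    """
    g = nx.MultiDiGraph()
    if nodes["id"].duplicated().any():
        dup = nodes.loc[nodes["id"].duplicated(), "id"].tolist()
        raise SchemaError(f"duplicate node ids: {dup}")
    for _, r in nodes.iterrows():
        g.add_node(str(r["id"]), node_type=r["node_type"], name=r.get("name", str(r["id"])))
    known = set(g.nodes)
    dangling = [
        (r["source"], r["target"])
        for _, r in edges.iterrows()
        if str(r["source"]) not in known or str(r["target"]) not in known
    ]
    if dangling:
        raise SchemaError(f"edge endpoint(s) not in node table: {dangling}")
    for _, r in edges.iterrows():
        attrs = {}
        raw = r.get("attributes")
        if isinstance(raw, str) and raw.strip():
            attrs = json.loads(raw)
        g.add_edge(str(r["source"]), str(r["target"]),
                   relation_type=r["relation_type"], **attrs)
    _validate(g)
    return KnowledgeGraph(g)


def load_graph(nodes_path, edges_path) -> KnowledgeGraph:
    """Load a schema-validated graph from node and edge TSV files."""
    nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    for col in ("id", "node_type"):
        if col not in nodes.columns:
            raise SchemaError(f"nodes table missing column {col!r}")
    for col in ("source", "target", "relation_type"):
        if col not in edges.columns:
            raise SchemaError(f"edges table missing column {col!r}")
    return build_graph(nodes, edges)


def write_graph(kg: KnowledgeGraph, nodes_path, edges_path) -> None:
    g = kg.graph
    nodes = pd.DataFrame(
        [
            {"id": n, "node_type": d["node_type"], "name": d.get("name", n)}
            for n, d in sorted(g.nodes(data=True))
        ]
    )
    rows = []
    for u, v, d in g.edges(data=True):
        attrs = {k: val for k, val in d.items() if k != "relation_type"}
        rows.append(
            {
                "source": u,
                "target": v,
                "relation_type": d["relation_type"],
                "attributes": json.dumps(attrs) if attrs else "",
            }
        )
    edges = pd.DataFrame(rows).sort_values(["source", "target", "relation_type"])
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# queries


def _bfs_edges(kg: KnowledgeGraph, seeds: set[str], relations: set[str], steps: int):
    """Edges of the requested relation types within ``steps`` hops of seeds.

    Traversal ignores edge direction (a compound seed reaches the enzyme
    catalysing it).
    """
    g = kg.graph
    frontier = {s for s in seeds if s in g}
    visited = set(frontier)
    picked = []
    for _ in range(steps):
        nxt = set()
        for u, v, key, d in g.edges(keys=True, data=True):
            if d["relation_type"] not in relations:
                continue
            if u in frontier or v in frontier:
                if (u, v, key) not in {p[:3] for p in picked}:
                    picked.append((u, v, key, d))
                for n in (u, v):
                    if n not in visited:
                        nxt.add(n)
        visited |= nxt
        frontier = visited  # widen: next hop may start anywhere reached
        if not nxt:
            break
    return picked


def _to_network(kg: KnowledgeGraph, picked) -> WeightedNetwork:
    nodes = {}
    edges = []
    for u, v, _key, d in picked:
        nodes[u] = kg.node_type(u)
        nodes[v] = kg.node_type(v)
        edges.append((u, v, 1.0, d["relation_type"]))
    net = WeightedNetwork.from_edges(edges, kind="knowledge", directed=True)
    for n, t in nodes.items():
        net.graph.nodes[n]["node_type"] = t
    return net


def query_simple_network(
    kg: KnowledgeGraph, seeds, relation_type: str, steps: int = 1
) -> WeightedNetwork:
    """Subnetwork of a single relation type around the seed entities."""
    if relation_type not in RELATION_SCHEMA:
        raise SchemaError(f"unknown relation {relation_type!r}")
    seeds = set(map(str, seeds))
    present = seeds & set(kg.graph.nodes)
    if not present:
        warnings.warn("no seed id found in the graph; returning an empty network")
        return WeightedNetwork.from_edges([], kind="knowledge", directed=True)
    return _to_network(kg, _bfs_edges(kg, present, {relation_type}, steps))


def query_heterogeneous_network(
    kg: KnowledgeGraph, seeds, relation_types, steps: int = 1
) -> WeightedNetwork:
    """Subnetwork mixing several relation types around the seeds.

    With e.g. ``{CONVERSION, CATALYSIS}`` and a gene seed, two steps walk
    gene -> enzyme -> compound, using enzymes as linking nodes.
    """
    relation_types = set(relation_types)
    if not relation_types:
        raise SchemaError("need at least one relation type")
    unknown = relation_types - set(RELATION_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown relation type(s): {sorted(unknown)}")
    seeds = set(map(str, seeds))
    present = seeds & set(kg.graph.nodes)
    if not present:
        warnings.warn("no seed id found in the graph; returning an empty network")
        return WeightedNetwork.from_edges([], kind="knowledge", directed=True)
    return _to_network(kg, _bfs_edges(kg, present, relation_types, steps))


# ---------------------------------------------------------------------------
# annotation sets and identifier mapping


def annotation_sets_from_graph(kg: KnowledgeGraph, entity_type: str = "compound"):
    """One AnnotationSet per pathway node, from its ANNOTATION edges.

    Only members of the requested entity type are collected; pathways
    annotating no such entity are dropped.
    """
    from .core_data import AnnotationSet

    sets = []
    for node, data in sorted(kg.graph.nodes(data=True)):
        if data["node_type"] != "pathway":
            continue
        members = {
            v
            for _, v, d in kg.graph.out_edges(node, data=True)
            if d["relation_type"] == "ANNOTATION" and kg.node_type(v) == entity_type
        }
        if members:
            sets.append(
                AnnotationSet(node, data.get("name", node), frozenset(members), "pathway")
            )
    return sets


def map_identifiers(ids, mapping: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Translate ids through a two-column mapping table.

    Returns ``(mapped, unmapped)``.  One-to-many mappings expand (with a
    warning); ids absent from the table land in the unmapped report.
    """
    src, dst = mapping.columns[:2]
    lookup: dict[str, list[str]] = {}
    for _, r in mapping.iterrows():
        lookup.setdefault(str(r[src]), []).append(str(r[dst]))
    mapped, unmapped = [], []
    for i in map(str, ids):
        if i in lookup:
            targets = lookup[i]
            if len(targets) > 1:
                warnings.warn(f"id {i!r} maps to {len(targets)} targets; all kept")
            mapped.extend(targets)
        else:
            unmapped.append(i)
    return mapped, unmapped
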