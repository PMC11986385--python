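"""Weighted property-graph construction, ranking queries, and serialization.

Nodes are fused concepts (one per distinct concept-and-type), edges are
directed canonical relations. An edge's ``weight`` is the number of distinct
source documents supporting it — repeated assertions within one document do
not inflate it (a per-instance count is available via ``dedup_per_doc=False``)
— and its ``provenance`` lists those documents. The in-process store is a
:class:`networkx.MultiDiGraph` keyed by relation, so no database server is
required; exports to GraphML, edge-list CSV and a Cypher ``CREATE`` script
feed external tooling (the Cypher dialect backtick-quotes relation names,
matching property-graph queries like ``MATCH ()-[r:`has symptom`]->()``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
from pydantic import BaseModel

from .errors import GraphBuildError, UnknownRelationError
from .fusion import AlignmentResult, NormalizationRules, DEFAULT_RULES, normalize_name
from .models import Triple
from .ontology import Schema, canonicalize_relation

_RELSEP = ";"
_PROVSEP = "|"


class ResolvedTriple(BaseModel):
    """A validated triple whose arguments are resolved to concept nodes."""

    subject_id: str
    subject_label: str
    subject_name: str
    relation: str
    object_id: str
    object_label: str
    object_name: str
    doc_id: str


def _node_key(node_id: str, label: str) -> str:
    return f"{label}{_PROVSEP}{node_id}"


class KnowledgeGraph:
    """Typed concept nodes and directed weighted relation edges."""

    def __init__(self, relations: Sequence[str] = (), schema_version: str = "1.0"):
        self.g = nx.MultiDiGraph()
        self.relations: set[str] = set(relations)
        self.schema_version = schema_version

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: str, label: str, name: str = "") -> str:
        key = _node_key(node_id, label)
        if key not in self.g:
            self.g.add_node(key, node_id=node_id, label=label, name=name or node_id)
        return key

    def add_support(
        self, src_key: str, relation: str, dst_key: str, doc_id: str
    ) -> None:
        """Register one supporting (document, source, relation, target) instance."""
        if self.g.has_edge(src_key, dst_key, key=relation):
            data = self.g.edges[src_key, dst_key, relation]
            data["_docs"].append(doc_id)
        else:
            self.g.add_edge(
                src_key, dst_key, key=relation, relation=relation, _docs=[doc_id]
            )
        self.relations.add(relation)

    def finalize(self, dedup_per_doc: bool = True) -> "KnowledgeGraph":
        """Compute weights and provenance from accumulated support."""
        for _, _, data in self.g.edges(data=True):
            docs = data.pop("_docs", None)
            if docs is None:
                continue
            distinct = sorted(set(docs))
            data["provenance"] = distinct
            data["n_instances"] = len(docs)
            data["weight"] = len(distinct) if dedup_per_doc else len(docs)
        return self

    # -- views --------------------------------------------------------------

    @property
    def node_count(self) -> int:
        return self.g.number_of_nodes()

    @property
    def edge_count(self) -> int:
        """Merged edges: one per distinct (source, relation, target)."""
        return self.g.number_of_edges()

    @property
    def instance_count(self) -> int:
        """Accepted assertion instances before per-document merging."""
        return sum(d.get("n_instances", 1) for _, _, d in self.g.edges(data=True))

    def nodes(self) -> list[dict]:
        return sorted(
            (dict(self.g.nodes[k]) for k in self.g.nodes),
            key=lambda n: (n["label"], n["node_id"]),
        )

    def edges(self) -> list[dict]:
        out = []
        for u, v, k, d in self.g.edges(keys=True, data=True):
            out.append(
                {
                    "source": self.g.nodes[u]["node_id"],
                    "source_label": self.g.nodes[u]["label"],
                    "source_name": self.g.nodes[u]["name"],
                    "relation": k,
                    "target": self.g.nodes[v]["node_id"],
                    "target_label": self.g.nodes[v]["label"],
                    "target_name": self.g.nodes[v]["name"],
                    "weight": d.get("weight", 1),
                    "provenance": list(d.get("provenance", [])),
                    "n_instances": d.get("n_instances", 1),
                }
            )
        out.sort(key=lambda e: (e["relation"], e["source_label"], e["source"],
                                e["target_label"], e["target"]))
        return out

    def stats(self) -> dict:
        return {
            "nodes": self.node_count,
            "edges_merged": self.edge_count,
            "edge_instances": self.instance_count,
            "relations": sorted(
                {k for _, _, k in self.g.edges(keys=True)}
            ),
        }

    # -- equality (canonical comparison) ------------------------------------

    def _canonical(self):
        nodes = {k: (d["node_id"], d["label"], d["name"])
                 for k, d in self.g.nodes(data=True)}
        edges = {
            (u, k, v): (d.get("weight", 1), tuple(d.get("provenance", [])))
            for u, v, k, d in self.g.edges(keys=True, data=True)
        }
        return nodes, edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self._canonical() == other._canonical()

    def diff(self, other: "KnowledgeGraph") -> dict:
        """Human-readable difference summary (for test failure messages)."""
        n1, e1 = self._canonical()
        n2, e2 = other._canonical()
        return {
            "nodes_only_self": sorted(set(n1) - set(n2)),
            "nodes_only_other": sorted(set(n2) - set(n1)),
            "edges_only_self": sorted(set(e1) - set(e2)),
            "edges_only_other": sorted(set(e2) - set(e1)),
            "weight_mismatch": sorted(
                k for k in set(e1) & set(e2) if e1[k][0] != e2[k][0]
            ),
        }


def resolve_triples(
    triples: Sequence[Triple],
    alignment: AlignmentResult,
    schema: Schema,
    rules: NormalizationRules = DEFAULT_RULES,
) -> list[ResolvedTriple]:
    """Map each validated triple's arguments to their fused clusters.

    Triple relations must already be canonical; argument entity types come
    from the relation's default typing (matching how mentions were derived).
    An argument with no cluster is a hard error naming the triple — silent
    drops here would break weight conservation.
    """
    resolved: list[ResolvedTriple] = []
    for t in triples:
        rdef = schema.relation(t.relation)
        stype = rdef.default_subject_type or "Diseases"
        otype = rdef.default_object_type or "Diseases"
        sc = alignment.cluster_of(t.subject, stype, rules)
        oc = alignment.cluster_of(t.object, otype, rules)
        if sc is None or oc is None:
            raise GraphBuildError(
                f"unresolved argument in triple {t.key()!r} "
                f"(subject cluster: {sc is not None}, object: {oc is not None})"
            )
        resolved.append(
            ResolvedTriple(
                subject_id=sc.node_id,
                subject_label=sc.etype,
                subject_name=sc.canonical_surface,
                relation=t.relation,
                object_id=oc.node_id,
                object_label=oc.etype,
                object_name=oc.canonical_surface,
                doc_id=t.doc_id,
            )
        )
    return resolved


def build_graph(
    triples: Sequence[ResolvedTriple],
    schema: Schema,
    dedup_per_doc: bool = True,
) -> KnowledgeGraph:
    """Build the weighted property graph from resolved triples.

    One node per distinct (concept, type); one edge per distinct
    (source, relation, target) with weight = number of distinct supporting
    documents (or raw instance count when ``dedup_per_doc`` is off).
    Node and edge orderings in exports are deterministic.
    """
    kg = KnowledgeGraph(
        relations=schema.canonical_relation_names, schema_version=schema.version
    )
    support: dict[tuple[str, str, str], list[str]] = {}
    for rt in triples:
        if rt.relation not in kg.relations:
            raise GraphBuildError(f"relation {rt.relation!r} not in schema")
        skey = kg.add_node(rt.subject_id, rt.subject_label, rt.subject_name)
        okey = kg.add_node(rt.object_id, rt.object_label, rt.object_name)
        support.setdefault((skey, rt.relation, okey), []).append(rt.doc_id)
    for (skey, rel, okey), docs in sorted(support.items()):
        for doc in docs:
            kg.add_support(skey, rel, okey, doc)
    return kg.finalize(dedup_per_doc=dedup_per_doc)


def top_edges(
    g: KnowledgeGraph,
    relation: str,
    k: Optional[int] = None,
    order: str = "desc",
    schema: Optional[Schema] = None,
) -> list[dict]:
    """Rank the edges of one relation by weight.

    ``relation`` may be an alias (e.g. ``has complication``) when a schema is
    supplied. Ties break lexicographically on (source, target); at most ``k``
    edges are returned (all of them when ``k`` is None or exceeds the count).
    """
    if order not in ("asc", "desc"):
        raise ValueError(f"order must be 'asc' or 'desc', got {order!r}")
    canonical = canonicalize_relation(relation, schema) if schema else relation
    if canonical not in g.relations:
        raise UnknownRelationError(relation)
    edges = [e for e in g.edges() if e["relation"] == canonical]
    edges.sort(
        key=lambda e: (
            -e["weight"] if order == "desc" else e["weight"],
            e["source"],
            e["target"],
        )
    )
    return edges if k is None else edges[:k]


def retrieve_subgraph(
    g: KnowledgeGraph,
    seeds: Sequence[str],
    radius: int = 1,
    rules: NormalizationRules = DEFAULT_RULES,
) -> KnowledgeGraph:
    """Neighborhood retrieval for graph-augmented generation.

    Seeds are matched against node names and ids by fusion normalization +
    exact match; the result is the induced subgraph of every node within
    ``radius`` undirected hops of a matched node. Radius 0 returns the
    matched nodes only, without edges. No seed match yields an empty graph.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    targets = {normalize_name(s, rules) for s in seeds}
    matched = [
        key
        for key, d in g.g.nodes(data=True)
        if normalize_name(d["name"], rules) in targets
        or normalize_name(d["node_id"], rules) in targets
    ]
    out = KnowledgeGraph(relations=g.relations, schema_version=g.schema_version)
    if not matched:
        return out
    undirected = g.g.to_undirected(as_view=True)
    keep: set[str] = set()
    for key in matched:
        lengths = nx.single_source_shortest_path_length(undirected, key, cutoff=radius)
        keep.update(lengths)
    for key in sorted(keep):
        d = g.g.nodes[key]
        out.add_node(d["node_id"], d["label"], d["name"])
    if radius > 0:
        for u, v, k, d in g.g.edges(keys=True, data=True):
            if u in keep and v in keep:
                out.g.add_edge(u, v, key=k, relation=k, **{
                    kk: vv for kk, vv in d.items() if kk != "relation"
                })
                out.relations.add(k)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def export_graph(g: KnowledgeGraph, path: Union[str, Path], fmt: str = "graphml") -> None:
    """Write the graph as ``graphml``, ``edgelist_csv`` or ``cypher``.

    GraphML and edge-list CSV round-trip losslessly through
    :func:`import_graph` for graphs built by :func:`build_graph`; the Cypher
    export emits ``CREATE`` statements with backtick-quoted relation names.
    """
    p = Path(path)
    if fmt == "graphml":
        h = nx.MultiDiGraph()
        h.graph["relations"] = _RELSEP.join(sorted(g.relations))
        h.graph["schema_version"] = g.schema_version
        for key, d in g.g.nodes(data=True):
            h.add_node(key, node_id=d["node_id"], label=d["label"], name=d["name"])
        for u, v, k, d in g.g.edges(keys=True, data=True):
            h.add_edge(
                u, v, key=k,
                relation=k,
                weight=int(d.get("weight", 1)),
                n_instances=int(d.get("n_instances", 1)),
                provenance=_PROVSEP.join(d.get("provenance", [])),
            )
        nx.write_graphml(h, p)
    elif fmt == "edgelist_csv":
        import csv

        with p.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["source", "source_label", "source_name", "relation",
                 "target", "target_label", "target_name",
                 "weight", "n_instances", "provenance"]
            )
            for e in g.edges():
                writer.writerow(
                    [e["source"], e["source_label"], e["source_name"],
                     e["relation"], e["target"], e["target_label"],
                     e["target_name"], e["weight"], e["n_instances"],
                     _PROVSEP.join(e["provenance"])]
                )
    elif fmt == "cypher":
        lines = []
        var: dict[str, str] = {}
        for i, n in enumerate(g.nodes()):
            v = f"n{i}"
            var[_node_key(n["node_id"], n["label"])] = v
            lines.append(
                f"CREATE ({v}:`{n['label']}` "
                f"{{node_id: {_cypher_str(n['node_id'])}, "
                f"name: {_cypher_str(n['name'])}}})"
            )
        for e in g.edges():
            u = var[_node_key(e["source"], e["source_label"])]
            v = var[_node_key(e["target"], e["target_label"])]
            prov = ", ".join(_cypher_str(d) for d in e["provenance"])
            lines.append(
                f"CREATE ({u})-[:`{e['relation']}` "
                f"{{weight: {e['weight']}, provenance: [{prov}]}}]->({v})"
            )
        p.write_text(";\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _cypher_str(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def import_graph(path: Union[str, Path], fmt: str = "graphml") -> KnowledgeGraph:
    """Read a graph written by :func:`export_graph` (graphml or edgelist_csv)."""
    p = Path(path)
    if fmt == "graphml":
        h = nx.read_graphml(p, force_multigraph=True)
        kg = KnowledgeGraph(
            relations=[
                r for r in h.graph.get("relations", "").split(_RELSEP) if r
            ],
            schema_version=h.graph.get("schema_version", "1.0"),
        )
        for key, d in h.nodes(data=True):
            kg.add_node(d["node_id"], d["label"], d.get("name", d["node_id"]))
        for u, v, k, d in h.edges(keys=True, data=True):
            rel = d.get("relation", k)
            prov = [x for x in d.get("provenance", "").split(_PROVSEP) if x]
            kg.g.add_edge(
                u, v, key=rel, relation=rel,
                weight=int(d.get("weight", 1)),
                n_instances=int(d.get("n_instances", 1)),
                provenance=prov,
            )
            kg.relations.add(rel)
        return kg
    if fmt == "edgelist_csv":
        import csv

        kg = KnowledgeGraph()
        with p.open("r", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                skey = kg.add_node(row["source"], row["source_label"], row["source_name"])
                okey = kg.add_node(row["target"], row["target_label"], row["target_name"])
                prov = [x for x in row["provenance"].split(_PROVSEP) if x]
                kg.g.add_edge(
                    skey, okey, key=row["relation"], relation=row["relation"],
                    weight=int(row["weight"]),
                    n_instances=int(row["n_instances"]),
                    provenance=prov,
                )
                kg.relations.add(row["relation"])
        return kg
    raise ValueError(f"unknown import format {fmt!r}")
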