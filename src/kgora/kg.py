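"""Typed heterogeneous knowledge-graph model, I/O, metapath path enumeration.

The graph is a set of typed entity nodes (diseases, genes, compounds,
pathway/GO terms) joined by typed, optionally weighted edges.  Paths between
a disease query node and a candidate target gene are enumerated under a
metapath template — an ordered sequence of (relation type, next node type)
constraints — and the union of the highest-scoring paths forms the target's
evidence subgraph, the unit on which enrichment is later tested.

Edges are stored with their written (source, relation, target) orientation
but are traversed as undirected during metapath matching: biomedical
relations such as ``interacts_with`` carry no meaningful direction here.
Path scoring is a deterministic stand-in for upstream neural path weighting:
the product of edge weights along the path.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

NODE_TYPES = frozenset({"disease", "gene", "compound", "pathway_or_GO"})


class GraphFormatError(ValueError):
    """A node/edge table is malformed (missing columns, bad values)."""


class VocabularyError(GraphFormatError):
    """A node type outside the controlled vocabulary."""


class GraphIntegrityError(ValueError):
    """An edge references a node absent from the node table."""


class MetapathTypeError(TypeError):
    """Metapath endpoint types incompatible with the query/target nodes."""


class EmptySubgraphError(ValueError):
    """No path survives retention; a subgraph cannot be assembled."""


@dataclass(frozen=True)
class EntityNode:
    id: str
    node_type: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise VocabularyError(
                f"unknown node type {self.node_type!r} for node {self.id!r}; "
                f"expected one of {sorted(NODE_TYPES)}"
            )


@dataclass(frozen=True)
class TypedEdge:
    source: str
    relation: str
    target: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight) or not 0.0 <= self.weight <= 1.0:
            raise GraphFormatError(
                f"edge weight must be finite and in [0, 1], got {self.weight!r} "
                f"on {self.source}-[{self.relation}]->{self.target}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.relation, self.target)


class KnowledgeGraph:
    """Validated container of typed nodes and edges with an adjacency index."""

    def __init__(self, nodes: Iterable[EntityNode], edges: Iterable[TypedEdge]):
        self._nodes: dict[str, EntityNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise GraphIntegrityError(f"duplicate node id {node.id!r}")
            self._nodes[node.id] = node
        self._edges: list[TypedEdge] = []
        self._adj = nx.MultiGraph()
        self._adj.add_nodes_from(self._nodes)
        for edge in edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self._nodes:
                    raise GraphIntegrityError(
                        f"edge {edge.source}\t{edge.relation}\t{edge.target} "
                        f"references unknown node {endpoint!r}"
                    )
            self._edges.append(edge)
            self._adj.add_edge(edge.source, edge.target, relation=edge.relation, edge=edge)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> tuple[EntityNode, ...]:
        return tuple(self._nodes.values())

    @property
    def edges(self) -> tuple[TypedEdge, ...]:
        return tuple(self._edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> EntityNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"node {node_id!r} not in graph") from None

    def node_type(self, node_id: str) -> str:
        return self.node(node_id).node_type

    def node_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for node in self._nodes.values():
            counts[node.node_type] = counts.get(node.node_type, 0) + 1
        return counts

    def neighbors(self, node_id: str, relation: str) -> Iterable[tuple[str, TypedEdge]]:
        """Undirected neighbours of ``node_id`` reachable over ``relation``."""
        for _, other, data in self._adj.edges(node_id, data=True):
            if data["relation"] == relation:
                yield other, data["edge"]

    # -- I/O -------------------------------------------------------------
    @classmethod
    def load(cls, node_table_path: str | Path, edge_table_path: str | Path) -> "KnowledgeGraph":
        node_df = pd.read_csv(node_table_path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("id", "type", "label"):
            if col not in node_df.columns:
                raise GraphFormatError(f"node table missing required column {col!r}")
        edge_df = pd.read_csv(edge_table_path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("source", "relation", "target"):
            if col not in edge_df.columns:
                raise GraphFormatError(f"edge table missing required column {col!r}")
        nodes = [
            EntityNode(id=r.id, node_type=r.type, label=r.label)
            for r in node_df.itertuples(index=False)
        ]
        edges = []
        for row in edge_df.itertuples(index=False):
            weight = 1.0
            if "weight" in edge_df.columns and row.weight != "":
                try:
                    weight = float(row.weight)
                except ValueError:
                    raise GraphFormatError(f"non-numeric edge weight {row.weight!r}") from None
            edges.append(TypedEdge(row.source, row.relation, row.target, weight))
        return cls(nodes, edges)

    def write(self, node_table_path: str | Path, edge_table_path: str | Path) -> None:
        node_df = pd.DataFrame(
            [(n.id, n.node_type, n.label) for n in self._nodes.values()],
            columns=["id", "type", "label"],
        )
        edge_df = pd.DataFrame(
            [(e.source, e.relation, e.target, repr(e.weight)) for e in self._edges],
            columns=["source", "relation", "target", "weight"],
        )
        node_df.to_csv(node_table_path, sep="\t", index=False)
        edge_df.to_csv(edge_table_path, sep="\t", index=False)


def load_graph(node_table_path: str | Path, edge_table_path: str | Path) -> KnowledgeGraph:
    """Load and validate a knowledge graph from node/edge TSV tables."""
    return KnowledgeGraph.load(node_table_path, edge_table_path)


@dataclass(frozen=True)
class Metapath:
    """Template constraining admissible paths: (relation, next node type) steps.

    ``start_type`` is the type of the query node; for disease->target queries
    the final step's node type must be ``gene``.
    """

    steps: tuple[tuple[str, str], ...]
    start_type: str = "disease"

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("metapath must have at least one step")
        if self.start_type not in NODE_TYPES:
            raise VocabularyError(f"unknown metapath start type {self.start_type!r}")
        for relation, node_type in self.steps:
            if node_type not in NODE_TYPES:
                raise VocabularyError(f"unknown metapath step node type {node_type!r}")

    @property
    def end_type(self) -> str:
        return self.steps[-1][1]

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class PathInstance:
    node_ids: tuple[str, ...]
    edge_refs: tuple[TypedEdge, ...]
    score: float

    @property
    def query_id(self) -> str:
        return self.node_ids[0]

    @property
    def target_id(self) -> str:
        return self.node_ids[-1]


def score_path(path_edges: Sequence[TypedEdge]) -> float:
    """Product of edge weights along the path (deterministic path score).

    With equal weights the score is non-increasing in path length, so the
    retention step prefers short, high-confidence evidence paths.
    """
    score = 1.0
    for edge in path_edges:
        score *= edge.weight
    return score


def enumerate_metapath_instances(
    graph: KnowledgeGraph,
    query_id: str,
    target_id: str,
    metapath: Metapath,
    max_instances: int | None = None,
) -> list[PathInstance]:
    """All simple paths from query to target conforming to the metapath.

    Returned in deterministic order: score descending, then lexicographic
    node-id sequence.  Paths revisiting a node are excluded, as are duplicate
    node sequences arising from parallel edges (the best-scoring edge
    combination is kept).  At most ``max_instances`` instances are returned.
    """
    if query_id not in graph:
        raise KeyError(f"query node {query_id!r} not in graph")
    if target_id not in graph:
        raise KeyError(f"target node {target_id!r} not in graph")
    if max_instances is not None and max_instances < 1:
        raise ValueError("max_instances must be >= 1")
    if graph.node_type(query_id) != metapath.start_type:
        raise MetapathTypeError(
            f"query node {query_id!r} has type {graph.node_type(query_id)!r}, "
            f"metapath starts at {metapath.start_type!r}"
        )
    if graph.node_type(target_id) != metapath.end_type:
        raise MetapathTypeError(
            f"target node {target_id!r} has type {graph.node_type(target_id)!r}, "
            f"metapath ends at {metapath.end_type!r}"
        )

    best: dict[tuple[str, ...], PathInstance] = {}

    def dfs(node: str, depth: int, visited: list[str], edges: list[TypedEdge]) -> None:
        if depth == len(metapath.steps):
            if node == target_id:
                node_seq = tuple(visited)
                candidate = PathInstance(node_seq, tuple(edges), score_path(edges))
                prev = best.get(node_seq)
                if prev is None or candidate.score > prev.score:
                    best[node_seq] = candidate
            return
        relation, next_type = metapath.steps[depth]
        for neighbor, edge in graph.neighbors(node, relation):
            if neighbor in visited:
                continue
            if graph.node_type(neighbor) != next_type:
                continue
            visited.append(neighbor)
            edges.append(edge)
            dfs(neighbor, depth + 1, visited, edges)
            visited.pop()
            edges.pop()

    dfs(query_id, 0, [query_id], [])
    ordered = sorted(best.values(), key=lambda p: (-p.score, p.node_ids))
    if max_instances is not None:
        ordered = ordered[:max_instances]
    return ordered


@dataclass(frozen=True)
class Subgraph:
    """Evidence subgraph for one (target, query) pair.

    ``gene_set`` is the set of gene-type nodes in the subgraph; by default the
    target gene itself is excluded so that a target which is itself a curated
    gene cannot enrich its own subgraph.
    """

    target_id: str
    query_id: str
    node_ids: frozenset[str] = field(default_factory=frozenset)
    edge_refs: frozenset[tuple[str, str, str]] = field(default_factory=frozenset)
    gene_set: frozenset[str] = field(default_factory=frozenset)


def assemble_subgraph(
    paths: Sequence[PathInstance],
    graph: KnowledgeGraph,
    *,
    top_m: int | None = None,
    min_score: float | None = None,
    include_target: bool = False,
) -> Subgraph:
    """Union the retained paths into one evidence subgraph.

    Retention keeps the ``top_m`` paths by (score desc, node-id sequence asc)
    or all paths with score >= ``min_score``; with neither given, all paths
    are retained.
    """
    if not paths:
        raise EmptySubgraphError("no paths supplied")
    queries = {p.query_id for p in paths}
    targets = {p.target_id for p in paths}
    if len(queries) != 1 or len(targets) != 1:
        raise ValueError(
            f"paths mix queries/targets: queries={sorted(queries)}, targets={sorted(targets)}"
        )
    retained = sorted(paths, key=lambda p: (-p.score, p.node_ids))
    if min_score is not None:
        retained = [p for p in retained if p.score >= min_score]
    if top_m is not None:
        retained = retained[:top_m]
    if not retained:
        raise EmptySubgraphError("no path survives retention")
    query_id, target_id = queries.pop(), targets.pop()
    node_ids = frozenset(n for p in retained for n in p.node_ids)
    edge_refs = frozenset(e.key for p in retained for e in p.edge_refs)
    gene_set = frozenset(
        n for n in node_ids if graph.node_type(n) == "gene" and (include_target or n != target_id)
    )
    return Subgraph(target_id, query_id, node_ids, edge_refs, gene_set)


# -- subgraph serialization (JSON-lines) ---------------------------------

def write_subgraphs(subgraphs: Iterable[Subgraph], path: str | Path) -> None:
    """One JSON object per line: target_id, query_id, nodes, edges, genes."""
    with open(path, "w") as fh:
        for sg in subgraphs:
            record = {
                "target_id": sg.target_id,
                "query_id": sg.query_id,
                "nodes": sorted(sg.node_ids),
                "edges": sorted(list(e) for e in sg.edge_refs),
                "genes": sorted(sg.gene_set),
            }
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def read_subgraphs(path: str | Path, graph: KnowledgeGraph | None = None) -> list[Subgraph]:
    """Read subgraphs from JSON-lines.

    If a record lacks an explicit ``genes`` field, the gene set is derived
    from node types in ``graph`` (target excluded).
    """
    out: list[Subgraph] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            nodes = frozenset(rec["nodes"])
            if "genes" in rec:
                genes = frozenset(rec["genes"])
            elif graph is not None:
                genes = frozenset(
                    n for n in nodes
                    if graph.node_type(n) == "gene" and n != rec["target_id"]
                )
            else:
                raise GraphFormatError(
                    "subgraph record lacks 'genes' and no graph given to derive them"
                )
            out.append(
                Subgraph(
                    target_id=rec["target_id"],
                    query_id=rec["query_id"],
                    node_ids=nodes,
                    edge_refs=frozenset(tuple(e) for e in rec.get("edges", [])),
                    gene_set=genes,
                )
            )
    return out
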