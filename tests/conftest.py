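import math

import numpy as np
import pytest

from kgora.kg import EntityNode, KnowledgeGraph, TypedEdge


@pytest.fixture
def toy_graph():
    """D -[associated_with]- G1 -[interacts_with]- G2, plus a compound spur."""
    nodes = [
        EntityNode("D", "disease", "disease D"),
        EntityNode("G1", "gene", "gene 1"),
        EntityNode("G2", "gene", "gene 2"),
        EntityNode("C1", "compound", "compound 1"),
    ]
    edges = [
        TypedEdge("D", "associated_with", "G1", 0.9),
        TypedEdge("G1", "interacts_with", "G2", 0.8),
        TypedEdge("C1", "targets", "G2", 0.7),
    ]
    return KnowledgeGraph(nodes, edges)


def random_typed_graph(seed: int, n_nodes: int = 12, edge_prob: float = 0.25) -> KnowledgeGraph:
    """Small random typed graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    types = ["disease", "gene", "gene", "gene", "compound", "pathway_or_GO"]
    relations = ["associated_with", "interacts_with", "participates_in", "targets"]
    nodes = [
        EntityNode(f"N{i:02d}", types[rng.integers(len(types))], f"node {i}")
        for i in range(n_nodes)
    ]
    # force at least one disease and two genes
    nodes[0] = EntityNode("N00", "disease", "query disease")
    nodes[1] = EntityNode("N01", "gene", "gene a")
    nodes[2] = EntityNode("N02", "gene", "gene b")
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                rel = relations[rng.integers(len(relations))]
                w = float(np.round(rng.uniform(0.1, 1.0), 3))
                edges.append(TypedEdge(nodes[i].id, rel, nodes[j].id, w))
    return KnowledgeGraph(nodes, edges)


def brute_force_metapath_paths(graph: KnowledgeGraph, query_id, target_id, metapath):
    """Independent DFS oracle: undirected traversal over the raw edge list."""
    adjacency = {}
    for edge in graph.edges:
        adjacency.setdefault(edge.source, []).append((edge.target, edge))
        adjacency.setdefault(edge.target, []).append((edge.source, edge))
    found = {}

    def walk(node, depth, nodes_so_far, weight):
        if depth == len(metapath.steps):
            if node == target_id:
                seq = tuple(nodes_so_far)
                if seq not in found or weight > found[seq]:
                    found[seq] = weight
            return
        relation, next_type = metapath.steps[depth]
        for neighbor, edge in adjacency.get(node, []):
            if edge.relation != relation:
                continue
            if graph.node_type(neighbor) != next_type:
                continue
            if neighbor in nodes_so_far:
                continue
            walk(neighbor, depth + 1, nodes_so_far + [neighbor], weight * edge.weight)

    walk(query_id, 0, [query_id], 1.0)
    return found  # node sequence -> best score


def brute_force_min_distance(res_a, res_b) -> float:
    """All-pairs minimum with pure-python loops (contact oracle)."""
    best = math.inf
    for xa in res_a.coords:
        for xb in res_b.coords:
            d = math.dist(tuple(xa), tuple(xb))
            best = min(best, d)
    return best
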