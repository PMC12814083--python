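"""Graph model, TSV I/O, metapath enumeration, and subgraph assembly."""

import itertools

import pytest

from kgora.kg import (
    EmptySubgraphError,
    EntityNode,
    GraphFormatError,
    GraphIntegrityError,
    KnowledgeGraph,
    Metapath,
    MetapathTypeError,
    PathInstance,
    TypedEdge,
    VocabularyError,
    assemble_subgraph,
    enumerate_metapath_instances,
    load_graph,
    read_subgraphs,
    score_path,
    write_subgraphs,
)

from conftest import brute_force_metapath_paths, random_typed_graph

DG_METAPATH = Metapath((("associated_with", "gene"), ("interacts_with", "gene")))


class TestGraphModel:
    def test_toy_load_counts(self, tmp_path):
        (tmp_path / "nodes.tsv").write_text(
            "id\ttype\tlabel\nD\tdisease\td\nG1\tgene\tg1\nG2\tgene\tg2\n"
        )
        (tmp_path / "edges.tsv").write_text(
            "source\trelation\ttarget\nD\tassociated_with\tG1\nG1\tinteracts_with\tG2\n"
        )
        graph = load_graph(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        assert len(graph.nodes) == 3
        assert len(graph.edges) == 2
        assert graph.node_type_counts() == {"disease": 1, "gene": 2}
        # missing weight column defaults to 1.0
        assert all(e.weight == 1.0 for e in graph.edges)

    def test_dangling_edge_rejected(self, tmp_path):
        (tmp_path / "nodes.tsv").write_text("id\ttype\tlabel\nD\tdisease\td\n")
        (tmp_path / "edges.tsv").write_text(
            "source\trelation\ttarget\nD\tassociated_with\tGX\n"
        )
        with pytest.raises(GraphIntegrityError, match="GX"):
            load_graph(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")

    def test_missing_column_is_format_error(self, tmp_path):
        (tmp_path / "nodes.tsv").write_text("id\tlabel\nD\td\n")
        (tmp_path / "edges.tsv").write_text("source\trelation\ttarget\n")
        with pytest.raises(GraphFormatError, match="type"):
            load_graph(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")

    def test_unknown_node_type_rejected(self):
        with pytest.raises(VocabularyError):
            EntityNode("X", "protein", "not in vocabulary")

    def test_edge_weight_range_enforced(self):
        with pytest.raises(GraphFormatError):
            TypedEdge("a", "r", "b", 1.5)
        with pytest.raises(GraphFormatError):
            TypedEdge("a", "r", "b", float("nan"))

    @pytest.mark.parametrize("seed", [0, 7])
    def test_tsv_round_trip_identity(self, tmp_path, seed):
        graph = random_typed_graph(seed)
        graph.write(tmp_path / "n.tsv", tmp_path / "e.tsv")
        again = load_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")
        assert sorted(graph.nodes, key=lambda n: n.id) == sorted(again.nodes, key=lambda n: n.id)
        assert sorted(e.key + (e.weight,) for e in graph.edges) == sorted(
            e.key + (e.weight,) for e in again.edges
        )

    def test_write_is_deterministic(self, tmp_path):
        graph = random_typed_graph(3)
        graph.write(tmp_path / "n1.tsv", tmp_path / "e1.tsv")
        graph.write(tmp_path / "n2.tsv", tmp_path / "e2.tsv")
        assert (tmp_path / "n1.tsv").read_bytes() == (tmp_path / "n2.tsv").read_bytes()
        assert (tmp_path / "e1.tsv").read_bytes() == (tmp_path / "e2.tsv").read_bytes()


class TestScorePath:
    def test_unit_weights_give_one(self):
        edges = [TypedEdge("a", "r", "b", 1.0), TypedEdge("b", "r", "c", 1.0)]
        assert score_path(edges) == 1.0

    def test_product_of_weights(self):
        edges = [TypedEdge("a", "r", "b", 0.5), TypedEdge("b", "r", "c", 0.5)]
        assert score_path(edges) == pytest.approx(0.25)

    def test_zero_weight_absorbs(self):
        edges = [TypedEdge("a", "r", "b", 0.9), TypedEdge("b", "r", "c", 0.0)]
        assert score_path(edges) == 0.0


class TestEnumerate:
    def test_toy_single_instance(self, toy_graph):
        paths = enumerate_metapath_instances(toy_graph, "D", "G2", DG_METAPATH)
        assert [p.node_ids for p in paths] == [("D", "G1", "G2")]
        assert paths[0].score == pytest.approx(0.9 * 0.8)

    def test_metapath_longer_than_graph_is_empty(self, toy_graph):
        long_mp = Metapath(
            (
                ("associated_with", "gene"),
                ("interacts_with", "gene"),
                ("interacts_with", "gene"),
                ("interacts_with", "gene"),
            )
        )
        assert enumerate_metapath_instances(toy_graph, "D", "G2", long_mp) == []

    def test_absent_nodes_raise_lookup_error(self, toy_graph):
        with pytest.raises(KeyError):
            enumerate_metapath_instances(toy_graph, "DX", "G2", DG_METAPATH)
        with pytest.raises(KeyError):
            enumerate_metapath_instances(toy_graph, "D", "GX", DG_METAPATH)

    def test_incompatible_endpoint_types_raise(self, toy_graph):
        with pytest.raises(MetapathTypeError):
            enumerate_metapath_instances(toy_graph, "G1", "G2", DG_METAPATH)
        with pytest.raises(MetapathTypeError):
            enumerate_metapath_instances(toy_graph, "D", "C1", DG_METAPATH)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_dfs(self, seed):
        """On random typed graphs (<=15 nodes), enumeration equals brute force
        for every metapath of length <= 4 over the relation vocabulary."""
        graph = random_typed_graph(seed, n_nodes=12)
        step_choices = [("associated_with", "gene"), ("interacts_with", "gene"),
                        ("participates_in", "pathway_or_GO"), ("targets", "compound")]
        gene_ids = [n.id for n in graph.nodes if n.node_type == "gene"]
        for length in (1, 2, 3, 4):
            for steps in itertools.product(step_choices, repeat=length):
                if steps[-1][1] != "gene":
                    continue
                metapath = Metapath(steps)
                for target in gene_ids[:3]:
                    expected = brute_force_metapath_paths(graph, "N00", target, metapath)
                    got = enumerate_metapath_instances(graph, "N00", target, metapath)
                    assert {p.node_ids for p in got} == set(expected)
                    for p in got:
                        assert p.score == pytest.approx(expected[p.node_ids])

    def test_order_and_truncation(self):
        nodes = [
            EntityNode("D", "disease", ""),
            EntityNode("G1", "gene", ""),
            EntityNode("G2", "gene", ""),
            EntityNode("GT", "gene", ""),
        ]
        edges = [
            TypedEdge("D", "associated_with", "G1", 0.9),
            TypedEdge("D", "associated_with", "G2", 0.5),
            TypedEdge("G1", "interacts_with", "GT", 1.0),
            TypedEdge("G2", "interacts_with", "GT", 1.0),
        ]
        graph = KnowledgeGraph(nodes, edges)
        paths = enumerate_metapath_instances(graph, "D", "GT", DG_METAPATH)
        assert [p.node_ids for p in paths] == [("D", "G1", "GT"), ("D", "G2", "GT")]
        top1 = enumerate_metapath_instances(graph, "D", "GT", DG_METAPATH, max_instances=1)
        assert [p.node_ids for p in top1] == [("D", "G1", "GT")]


class TestAssembleSubgraph:
    def test_single_path_excludes_target_from_gene_set(self, toy_graph):
        paths = enumerate_metapath_instances(toy_graph, "D", "G2", DG_METAPATH)
        sg = assemble_subgraph(paths, toy_graph)
        assert sg.node_ids == {"D", "G1", "G2"}
        assert sg.gene_set == {"G1"}
        sg_self = assemble_subgraph(paths, toy_graph, include_target=True)
        assert sg_self.gene_set == {"G1", "G2"}

    def test_union_without_duplication(self):
        nodes = [
            EntityNode("D", "disease", ""),
            EntityNode("G1", "gene", ""),
            EntityNode("G2", "gene", ""),
            EntityNode("GT", "gene", ""),
        ]
        edges = [
            TypedEdge("D", "associated_with", "G1", 0.9),
            TypedEdge("G1", "interacts_with", "G2", 0.9),
            TypedEdge("G2", "interacts_with", "GT", 0.9),
            TypedEdge("G1", "interacts_with", "GT", 0.9),
        ]
        graph = KnowledgeGraph(nodes, edges)
        mp2 = Metapath((("associated_with", "gene"), ("interacts_with", "gene")))
        mp3 = Metapath(
            (("associated_with", "gene"), ("interacts_with", "gene"), ("interacts_with", "gene"))
        )
        paths = enumerate_metapath_instances(graph, "D", "GT", mp2) + \
            enumerate_metapath_instances(graph, "D", "GT", mp3)
        sg = assemble_subgraph(paths, graph)
        assert sg.node_ids == {"D", "G1", "G2", "GT"}
        assert sg.gene_set == {"G1", "G2"}
        for edge in sg.edge_refs:
            assert edge in {e.key for e in graph.edges}

    @pytest.mark.parametrize("seed", [0, 5])
    def test_top_m_retention_matches_sort_and_union(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        graph = KnowledgeGraph(
            [EntityNode("D", "disease", ""), EntityNode("GT", "gene", "")]
            + [EntityNode(f"G{i}", "gene", "") for i in range(20)],
            [],
        )
        paths = []
        for i in range(20):
            w = float(np.round(rng.uniform(0.1, 1.0), 3))
            edges = (
                TypedEdge("D", "associated_with", f"G{i}", w),
                TypedEdge(f"G{i}", "interacts_with", "GT", 1.0),
            )
            paths.append(PathInstance(("D", f"G{i}", "GT"), edges, score_path(edges)))
        sg = assemble_subgraph(paths, graph, top_m=5)
        best5 = sorted(paths, key=lambda p: (-p.score, p.node_ids))[:5]
        expected_nodes = {n for p in best5 for n in p.node_ids}
        assert sg.node_ids == expected_nodes

    def test_mixed_targets_rejected(self, toy_graph):
        p1 = PathInstance(("D", "G1"), (TypedEdge("D", "associated_with", "G1", 1.0),), 1.0)
        p2 = PathInstance(("D", "G2"), (TypedEdge("D", "associated_with", "G2", 1.0),), 1.0)
        with pytest.raises(ValueError, match="mix"):
            assemble_subgraph([p1, p2], toy_graph)

    def test_empty_retention_raises(self, toy_graph):
        paths = enumerate_metapath_instances(toy_graph, "D", "G2", DG_METAPATH)
        with pytest.raises(EmptySubgraphError):
            assemble_subgraph(paths, toy_graph, min_score=2.0)
        with pytest.raises(EmptySubgraphError):
            assemble_subgraph([], toy_graph)


class TestSubgraphSerialization:
    def test_jsonl_round_trip(self, tmp_path, toy_graph):
        paths = enumerate_metapath_instances(toy_graph, "D", "G2", DG_METAPATH)
        sg = assemble_subgraph(paths, toy_graph)
        write_subgraphs([sg], tmp_path / "sg.jsonl")
        loaded = read_subgraphs(tmp_path / "sg.jsonl")
        assert loaded == [sg]

    def test_byte_identical_serialization(self, tmp_path, toy_graph):
        paths = enumerate_metapath_instances(toy_graph, "D", "G2", DG_METAPATH)
        sg = assemble_subgraph(paths, toy_graph)
        write_subgraphs([sg], tmp_path / "a.jsonl")
        write_subgraphs([sg], tmp_path / "b.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()
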