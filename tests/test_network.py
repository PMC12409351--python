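from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from panphage.association import AssociationResult
from panphage.network import (
    EDGE_DISSOCIATION,
    EDGE_INTER_CLUSTER,
    EDGE_MEMBERSHIP,
    build_association_graph,
    export_network,
    filter_by_force,
    make_cluster_network,
    mcl_cluster,
)


def res(a, b, ca="bacterial_gene", cb="bacterial_gene", score_type="association", sig=True):
    return AssociationResult(
        entity_a=a, entity_b=b, category_a=ca, category_b=cb,
        score_type=score_type, observed_score=3, p_value=0.001,
        q_value=0.01 if sig else 0.5, significant=sig,
    )


class TestAssociationGraph:
    def test_empty(self):
        assert build_association_graph([]).number_of_nodes() == 0

    def test_triangle(self):
        g = build_association_graph([res("a", "b"), res("b", "c"), res("a", "c")])
        assert g.number_of_edges() == 3

    def test_dissociation_and_insignificant_excluded(self):
        g = build_association_graph(
            [res("a", "b", score_type="dissociation"), res("b", "c", sig=False)]
        )
        assert g.number_of_edges() == 0


class TestMcl:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        clusters = mcl_cluster(g)
        assert sorted(map(sorted, clusters)) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        assert mcl_cluster(g) == [["a", "b"]]

    def test_empty_graph(self):
        assert mcl_cluster(nx.Graph()) == []

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(25, 0.15, seed=7)
        clusters = mcl_cluster(g)
        flat = [n for c in clusters for n in c]
        assert sorted(flat) == sorted(g.nodes())
        assert len(flat) == len(set(flat))

    def test_disjoint_cliques_recovered_at_various_inflation(self):
        g = nx.Graph()
        for offset, size in ((0, 4), (10, 5), (20, 3)):
            members = [offset + i for i in range(size)]
            g.add_edges_from(
                (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
            )
        for inflation in (1.5, 2.0, 3.0):
            clusters = mcl_cluster(g, inflation=inflation)
            assert sorted(map(len, clusters), reverse=True) == [5, 4, 3]

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph(), inflation=1.0)


@pytest.fixture
def two_cluster_setup():
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(4)]
    categories = {n: "bacterial_gene" for n in a}
    categories |= {n: "phage" for n in b}
    cross = [res(a[0], b[0], "bacterial_gene", "phage"),
             res(a[1], b[1], "bacterial_gene", "phage")]
    return [a, b], cross, categories


class TestClusterNetwork:
    def test_force_worked_example(self, two_cluster_setup):
        clusters, cross, categories = two_cluster_setup
        net = make_cluster_network(clusters, cross, categories)
        (edge,) = [
            d for _, _, d in net.graph.edges(data=True)
            if d["kind"] == EDGE_INTER_CLUSTER
        ]
        assert edge["force"] == pytest.approx(1.0 + 2 / 20)

    def test_no_cross_pairs_no_edge(self, two_cluster_setup):
        clusters, _, categories = two_cluster_setup
        net = make_cluster_network(clusters, [], categories)
        assert net.edges_of_kind(EDGE_INTER_CLUSTER) == []

    def test_centre_kinds(self):
        clusters = [["p1", "p2"], ["g1", "g2", "p3"]]
        categories = {"p1": "phage", "p2": "phage", "p3": "phage",
                      "g1": "bacterial_gene", "g2": "bacterial_gene"}
        net = make_cluster_network(clusters, [], categories)
        kinds = {
            net.graph.nodes[c]["cluster_id"]: net.graph.nodes[c]["centre_kind"]
            for c in net.centre_nodes()
        }
        # ordering: C1 is the 3-member cluster
        assert kinds == {"C1": "mixed", "C2": "pure_phage"}

    def test_membership_edge_count_equals_clustered_nodes(self, two_cluster_setup):
        clusters, cross, categories = two_cluster_setup
        net = make_cluster_network(clusters, cross, categories)
        assert len(net.edges_of_kind(EDGE_MEMBERSHIP)) == 9

    def test_singletons_have_no_centre(self):
        net = make_cluster_network([["solo"]], [], {"solo": "bacterial_gene"})
        assert net.centre_nodes() == []
        assert "solo" in net.graph

    def test_dissociation_edges_between_entities(self):
        d = res("g1", "g2", score_type="dissociation")
        net = make_cluster_network([], [d], {"g1": "bacterial_gene", "g2": "bacterial_gene"})
        assert net.edges_of_kind(EDGE_DISSOCIATION) == [("g1", "g2")]

    def test_force_bounds(self):
        a = ["a0", "a1"]
        b = ["b0", "b1"]
        categories = {n: "bacterial_gene" for n in a + b}
        cross = [res(x, y) for x in a for y in b]  # all 4 cross pairs
        net = make_cluster_network([a, b], cross, categories)
        (edge,) = [
            d for _, _, d in net.graph.edges(data=True)
            if d["kind"] == EDGE_INTER_CLUSTER
        ]
        assert edge["force"] == pytest.approx(2.0)


class TestFilterByForce:
    def test_threshold_keeps_110_drops_105(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(4)]
        c = [f"c{i}" for i in range(5)]
        categories = {n: "bacterial_gene" for n in a + b + c}
        cross = [res(a[0], b[0]), res(a[1], b[1]), res(a[0], c[0])]
        # a-b force = 1 + 2/20 = 1.1 ; a-c force = 1 + 1/25 = 1.04
        net = make_cluster_network([a, b, c], cross, categories)
        kept = filter_by_force(net, 1.1)
        forces = [
            d["force"] for _, _, d in kept.graph.edges(data=True)
            if d["kind"] == EDGE_INTER_CLUSTER
        ]
        assert forces == [pytest.approx(1.1)]

    def test_threshold_one_is_identity_on_inter_edges(self, two_cluster_setup=None):
        a = [f"a{i}" for i in range(3)]
        b = [f"b{i}" for i in range(3)]
        categories = {n: "bacterial_gene" for n in a + b}
        net = make_cluster_network([a, b], [res(a[0], b[0])], categories)
        kept = filter_by_force(net, 1.0)
        assert kept.edges_of_kind(EDGE_INTER_CLUSTER) == net.edges_of_kind(EDGE_INTER_CLUSTER)

    def test_mixed_only_view_empty_without_mixed(self):
        a = [f"a{i}" for i in range(3)]
        categories = {n: "bacterial_gene" for n in a}
        net = make_cluster_network([a], [], categories)
        view = filter_by_force(net, 1.0, mixed_only=True)
        assert view.centre_nodes() == []

    def test_mixed_only_keeps_connected_neighbours(self):
        a = ["g1", "p1"]  # mixed
        b = ["g2", "g3"]  # pure, connected to mixed
        c = ["g4", "g5"]  # pure, unconnected
        categories = {"p1": "phage"} | {f"g{i}": "bacterial_gene" for i in range(1, 6)}
        cross = [res("g1", "g2"), res("p1", "g3")]  # a-b force 1.5
        net = make_cluster_network([a, b, c], cross, categories)
        view = filter_by_force(net, 1.1, mixed_only=True)
        kinds = {view.graph.nodes[n]["cluster_id"] for n in view.centre_nodes()}
        assert len(kinds) == 2
        assert "g4" not in view.graph


class TestExport:
    def test_graphml_round_trip_and_determinism(self, tmp_path, two_cluster_setup):
        clusters, cross, categories = two_cluster_setup
        net = make_cluster_network(clusters, cross, categories)
        p1 = export_network(net, tmp_path / "run1")
        p2 = export_network(net, tmp_path / "run2")
        assert p1["graphml"].read_bytes() == p2["graphml"].read_bytes()
        back = nx.read_graphml(p1["graphml"])
        assert sorted(back.nodes()) == sorted(net.graph.nodes())
        for n in net.graph.nodes():
            assert back.nodes[n]["node_type"] == net.graph.nodes[n]["node_type"]
        assert back.number_of_edges() == net.graph.number_of_edges()

    def test_empty_network(self, tmp_path):
        from panphage.network import ClusterNetwork

        paths = export_network(ClusterNetwork(), tmp_path / "empty")
        assert nx.read_graphml(paths["graphml"]).number_of_nodes() == 0

    def test_attribute_escaping(self, tmp_path):
        net = make_cluster_network(
            [["g1"]], [], {"g1": "bacterial_gene"},
            annotations={"g1": "weird\tannotation\nwith breaks"},
        )
        paths = export_network(net, tmp_path / "esc")
        for line in paths["nodes"].read_text().splitlines():
            assert line.count("\t") == 4
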