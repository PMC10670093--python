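import math

import networkx as nx
import numpy as np
import pytest

from oracles import brute_bridge_length
from xtalk.fixtures import planted_linker_fixture
from xtalk.mcode_clustering import ComplexResult
from xtalk.crosstalk_linker import (
    extract_witness_paths,
    score_cytosolic_linkers,
    select_tricompartment_cluster,
    write_witness_dot,
)
from xtalk.organelle_catalog import assign_primary_compartment, harmonize


def make_catalog(compartment_of):
    import pandas as pd

    rows = pd.DataFrame(
        [(s, c, "A") for s, c in compartment_of.items()],
        columns=["symbol", "compartment", "source"],
    )
    return assign_primary_compartment(harmonize([rows]))


def make_complex(members, rank):
    return ComplexResult(members=frozenset(members), seed=sorted(members)[0],
                         score=float(len(members)), rank=rank,
                         edge_count=0)


def random_tri_graph(seed, n=25, p=0.15):
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in range(n)})
    nodes = sorted(g.nodes)
    labels = {v: "mitochondria" for v in nodes}
    perm = rng.permutation(n)
    labels[nodes[perm[0]]] = "ER"
    for i in perm[1:1 + max(2, n // 4)]:
        labels[nodes[i]] = "cytosol"
    nx.set_node_attributes(g, labels, "compartment")
    return g


class TestSelectTricompartmentCluster:
    def test_first_cluster_with_all_three_compartments_wins(self):
        catalog = make_catalog({"m1": "mito", "m2": "mito", "c1": "cytosol",
                                "c2": "cytosol", "e1": "ER"})
        clusters = [
            make_complex({"m1", "m2"}, 1),
            make_complex({"m1", "c1"}, 2),
            make_complex({"m2", "c2", "e1"}, 3),
        ]
        selected, comp = select_tricompartment_cluster(clusters, catalog)
        assert selected.rank == 3
        assert comp == {"ER": 1, "mitochondria": 1, "cytosol": 1}

    def test_higher_ranked_of_two_qualifying_clusters_wins(self):
        catalog = make_catalog({"m1": "mito", "m2": "mito", "c1": "cytosol",
                                "c2": "cytosol", "e1": "ER", "e2": "ER"})
        clusters = [make_complex({"m1", "c1", "e1"}, 1),
                    make_complex({"m2", "c2", "e2"}, 2)]
        selected, _ = select_tricompartment_cluster(clusters, catalog)
        assert selected.rank == 1

    def test_no_qualifying_cluster_reports_diagnostics(self):
        catalog = make_catalog({"m1": "mito", "c1": "cytosol"})
        selected, diag = select_tricompartment_cluster(
            [make_complex({"m1", "c1"}, 1)], catalog
        )
        assert selected is None
        assert "compositions" in diag

    def test_reference_fixture_composition(self, screen_bundle):
        from xtalk.mcode_clustering import MCODEParams, find_complexes, top_k

        top = top_k(find_complexes(screen_bundle.graph, MCODEParams(fluff=True)), 3)
        selected, comp = select_tricompartment_cluster(top, screen_bundle.catalog)
        assert selected.size == 44
        assert comp == {"ER": 1, "mitochondria": 37, "cytosol": 6}


class TestScoreCytosolicLinkers:
    def test_minimal_relay_path(self, tri_path_graph):
        linkers = score_cytosolic_linkers(tri_path_graph)
        assert linkers[0].node == "C1"
        assert linkers[0].bridge_length == 2
        assert linkers[0].rank == 1

    def test_motif_bridge_length_and_top_rank(self, motif_graph):
        linkers = score_cytosolic_linkers(motif_graph)
        ddo = linkers[0]
        assert ddo.node == "DDO"
        assert ddo.bridge_length == 3  # two hops to the ER, one to a mito hub
        assert ddo.n_paths == 2

    def test_missing_compartment_rejected(self):
        g = nx.path_graph(["a", "b"])
        nx.set_node_attributes(
            g, {"a": "cytosol", "b": "mitochondria"}, "compartment"
        )
        with pytest.raises(ValueError, match="three compartments"):
            score_cytosolic_linkers(g)

    def test_unreachable_cytosolic_node_ranks_last(self, tri_path_graph):
        tri_path_graph.add_node("C9", compartment="cytosol")
        linkers = score_cytosolic_linkers(tri_path_graph)
        assert linkers[-1].node == "C9"
        assert math.isinf(linkers[-1].bridge_length)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_triple_enumeration(self, seed):
        g = random_tri_graph(seed)
        er = {v for v, c in g.nodes(data="compartment") if c == "ER"}
        mito = {v for v, c in g.nodes(data="compartment") if c == "mitochondria"}
        linkers = score_cytosolic_linkers(g)
        for l in linkers:
            assert l.bridge_length == brute_bridge_length(g, l.node, er, mito)

    def test_bridge_at_least_two_for_cytosolic_nodes(self):
        for seed in range(5):
            for l in score_cytosolic_linkers(random_tri_graph(seed)):
                if math.isfinite(l.bridge_length):
                    assert l.bridge_length >= 2

    def test_ranking_invariant_under_insertion_order(self):
        g = random_tri_graph(3)
        h = nx.Graph()
        h.add_nodes_from(sorted(g.nodes, reverse=True),)
        for v in h.nodes:
            h.nodes[v]["compartment"] = g.nodes[v]["compartment"]
        h.add_edges_from(sorted(g.edges, reverse=True))
        assert [l.node for l in score_cytosolic_linkers(g)] == \
               [l.node for l in score_cytosolic_linkers(h)]

    def test_sole_cut_vertex_ranks_first(self):
        # E - C - M1 - M2 and a far cytosolic bystander hanging off M2
        g = nx.Graph()
        g.add_edges_from([("E", "C"), ("C", "M1"), ("M1", "M2"), ("M2", "C9")])
        nx.set_node_attributes(
            g, {"E": "ER", "C": "cytosol", "M1": "mitochondria",
                "M2": "mitochondria", "C9": "cytosol"}, "compartment"
        )
        linkers = score_cytosolic_linkers(g)
        assert linkers[0].node == "C"

    def test_witness_paths_are_valid(self, motif_graph):
        l = score_cytosolic_linkers(motif_graph)[0]
        full = l.witness_er[:-1] + (l.node,) + l.witness_mito[1:]
        assert nx.is_simple_path(motif_graph, full)
        assert len(full) - 1 == l.bridge_length


class TestExtractWitnessPaths:
    def test_single_witness_on_path_graph(self, tri_path_graph):
        l = score_cytosolic_linkers(tri_path_graph)[0]
        wit = extract_witness_paths(tri_path_graph, l)
        assert wit == [[("E1", "ER"), ("C1", "cytosol"), ("M1", "mitochondria")]]

    def test_motif_has_two_witnesses_through_each_intermediate(self, motif_graph):
        l = score_cytosolic_linkers(motif_graph)[0]
        wit = extract_witness_paths(motif_graph, l)
        routes = {tuple(v for v, _ in w) for w in wit}
        assert routes == {
            ("SEC61A1", "IDE", "DDO", "UBA52"),
            ("SEC61A1", "UBA52", "DDO", "IDE"),
        }

    def test_max_paths_truncates_deterministically(self, motif_graph):
        l = score_cytosolic_linkers(motif_graph)[0]
        wit = extract_witness_paths(motif_graph, l, max_paths=1)
        assert len(wit) == 1
        assert [v for v, _ in wit[0]] == ["SEC61A1", "IDE", "DDO", "UBA52"]

    def test_infinite_linker_rejected(self, tri_path_graph):
        tri_path_graph.add_node("C9", compartment="cytosol")
        lonely = score_cytosolic_linkers(tri_path_graph)[-1]
        with pytest.raises(ValueError, match="infinite"):
            extract_witness_paths(tri_path_graph, lonely)


class TestLinkerRecovery:
    def test_planted_linker_found_in_most_regenerations(self):
        hits = 0
        for seed in range(10):
            _, g, truth = planted_linker_fixture(seed=seed)
            hits += score_cytosolic_linkers(g)[0].node == truth.planted_linker
        assert hits >= 9


def test_witness_dot_export_highlights_relay(tmp_path, motif_graph):
    linkers = score_cytosolic_linkers(motif_graph)
    path = tmp_path / "w.dot"
    write_witness_dot(motif_graph, linkers, path)
    text = path.read_text()
    assert text.startswith("graph")
    assert "color=red" in text
    assert '"DDO"' in text
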