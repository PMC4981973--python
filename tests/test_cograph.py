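"""P4 detection, minimum cograph editing, cotree construction and semantics."""

from __future__ import annotations

import random
from itertools import combinations

import networkx as nx
import pytest

from synterna.cograph import (
    Cotree,
    cograph_to_cotree,
    cotree_to_cograph,
    count_duplications,
    edit_to_cograph,
    find_p4,
    is_cograph,
)

from conftest import random_cotree


def brute_force_min_edit(G: nx.Graph, cap: int = 4) -> int:
    """Oracle: smallest number of pair flips making G P4-free, by exhaustive
    search over all edge-subset modifications of size 0..cap."""
    nodes = sorted(G.nodes)
    pairs = list(combinations(nodes, 2))
    for k in range(cap + 1):
        for subset in combinations(pairs, k):
            H = G.copy()
            for u, v in subset:
                if H.has_edge(u, v):
                    H.remove_edge(u, v)
                else:
                    H.add_edge(u, v)
            if not _has_p4(H):
                return k
    raise AssertionError("cap too small for oracle")


def _has_p4(G: nx.Graph) -> bool:
    nodes = list(G.nodes)
    for quad in combinations(nodes, 4):
        sub = G.subgraph(quad)
        degs = sorted(d for _, d in sub.degree)
        if degs == [1, 1, 2, 2] and nx.is_connected(sub):
            return True
    return False


class TestFindP4:
    def test_path_is_its_own_p4(self):
        G = nx.path_graph(["a", "b", "c", "d"])
        assert find_p4(G) == [("a", "b", "c", "d")]

    def test_complete_graph_is_cograph(self):
        assert find_p4(nx.complete_graph(4)) == []
        assert is_cograph(nx.complete_graph(6))

    def test_paw_has_no_p4(self):
        # triangle plus pendant vertex: exhaustive 4-subset check finds nothing
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)])
        assert find_p4(G) == []

    def test_p5_contains_two_p4s(self):
        G = nx.path_graph(5)
        assert len(find_p4(G)) == 2

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = random.Random(2)
        for _ in range(30):
            n = rng.randint(4, 8)
            G = nx.gnp_random_graph(n, 0.5, seed=rng.randint(0, 10**6))
            assert (find_p4(G) == []) == (not _has_p4(G))


class TestEditToCograph:
    def test_cograph_needs_no_edits(self):
        G = nx.complete_graph(5)
        assert edit_to_cograph(G).size == 0

    def test_single_p4_needs_one_edit(self):
        G = nx.path_graph(4)
        e = edit_to_cograph(G)
        assert e.size == 1
        assert is_cograph(e.apply(G))

    def test_components_edited_independently(self):
        g1 = nx.path_graph([0, 1, 2, 3])
        g2 = nx.path_graph([10, 11, 12, 13])
        total = sum(edit_to_cograph(G).size for G in (g1, g2))
        assert total == 2

    def test_minimality_against_brute_force(self):
        rng = random.Random(4)
        for _ in range(25):
            n = rng.randint(4, 8)
            base = cotree_to_cograph(random_cotree(rng, [f"v{i}" for i in range(n)]))
            for _ in range(rng.randint(0, 2)):  # perturb a known cograph
                u, v = rng.sample(sorted(base.nodes), 2)
                if base.has_edge(u, v):
                    base.remove_edge(u, v)
                else:
                    base.add_edge(u, v)
            e = edit_to_cograph(base)
            assert e.size == brute_force_min_edit(base)
            assert is_cograph(e.apply(base))

    def test_result_always_p4_free(self):
        rng = random.Random(6)
        for _ in range(20):
            G = nx.gnp_random_graph(7, 0.4, seed=rng.randint(0, 10**6))
            G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
            e = edit_to_cograph(G)
            assert find_p4(e.apply(G)) == []

    def test_greedy_fallback_above_bound_is_flagged(self):
        G = nx.path_graph(12)
        e = edit_to_cograph(G, exact_bound=8)
        assert not e.optimal
        assert is_cograph(e.apply(G))

    def test_editing_preserves_vertices(self):
        G = nx.path_graph(["w", "x", "y", "z"])
        H = edit_to_cograph(G).apply(G)
        assert set(H.nodes) == set(G.nodes)

    def test_species_aware_tie_break_avoids_conspecific_insertion(self):
        # P4 a1-b1-c1-a2 with a1,a2 conspecific: among the one-edit optima,
        # never pick the insertion {a1,a2}
        G = nx.path_graph(["a1", "b1", "c1", "a2"])
        sp = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        e = edit_to_cograph(G, species_of=sp)
        assert frozenset(("a1", "a2")) not in e.insertions


class TestCotree:
    def test_clique_is_single_series_node(self):
        G = nx.complete_graph(["x", "y", "z"])
        t = cograph_to_cotree(G)
        assert t.label == "S" and all(c.is_leaf for c in t.children)

    def test_edgeless_graph_is_single_parallel_node(self):
        G = nx.empty_graph(["x", "y", "z"])
        t = cograph_to_cotree(G)
        assert t.label == "D" and len(t.children) == 3

    def test_complete_tripartite_with_double_part(self):
        G = nx.complete_multipartite_graph(2, 1, 1)
        t = cograph_to_cotree(G)
        assert t.label == "S"
        labels = sorted((c.label or "leaf") for c in t.children)
        assert labels == ["D", "leaf", "leaf"]
        assert nx.is_isomorphic(cotree_to_cograph(t), G)

    def test_round_trip_graph_to_tree_to_graph(self):
        rng = random.Random(8)
        for _ in range(30):
            n = rng.randint(2, 10)
            G = cotree_to_cograph(random_cotree(rng, [f"v{i}" for i in range(n)]))
            H = cotree_to_cograph(cograph_to_cotree(G))
            assert set(H.nodes) == set(G.nodes)
            assert set(map(frozenset, H.edges)) == set(map(frozenset, G.edges))

    def test_non_cograph_rejected(self):
        with pytest.raises(ValueError):
            cograph_to_cotree(nx.path_graph(4))

    def test_canonical_no_adjacent_equal_labels(self):
        rng = random.Random(9)
        for _ in range(20):
            G = cotree_to_cograph(random_cotree(rng, [f"v{i}" for i in range(8)]))
            t = cograph_to_cotree(G)
            for node in t.iter_nodes():
                for child in node.children:
                    if not child.is_leaf:
                        assert child.label != node.label

    def test_newick_export(self):
        t = cograph_to_cotree(nx.complete_graph(["x", "y"]))
        assert t.to_newick() == "(x,y)S;"


class TestCountDuplications:
    def test_clique_one_gene_per_species_has_none(self):
        G = nx.complete_graph(["A_1", "B_1", "C_1"])
        sp = {g: g[0] for g in G.nodes}
        assert count_duplications(cograph_to_cotree(G), sp) == 0

    def test_parallel_root_over_two_conspecific_leaves(self):
        t = Cotree(label="D", children=[Cotree(leaf="A_1"), Cotree(leaf="A_2")])
        assert count_duplications(t, {"A_1": "A", "A_2": "A"}) == 1

    def test_nested_duplication_under_speciation(self):
        # series root over {parallel(x1,x2), y}: one duplication
        t = Cotree(
            label="S",
            children=[
                Cotree(label="D", children=[Cotree(leaf="A_x1"), Cotree(leaf="A_x2")]),
                Cotree(leaf="B_y"),
            ],
        )
        assert count_duplications(t, {"A_x1": "A", "A_x2": "A", "B_y": "B"}) == 1

    def test_multifurcating_parallel_counts_children_minus_one(self):
        t = Cotree(label="D", children=[Cotree(leaf=f"A_{i}") for i in range(4)])
        assert count_duplications(t) == 3

    def test_conspecific_series_lca_raises(self):
        G = nx.complete_graph(["A_1", "A_2", "B_1"])
        sp = {"A_1": "A", "A_2": "A", "B_1": "B"}
        with pytest.raises(ValueError):
            count_duplications(cograph_to_cotree(G), sp)
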