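"""Candidate graph construction, distance pruning, cluster joining, comparison."""

from __future__ import annotations

import random

import pytest

from synterna.graph import (
    DistanceParams,
    build_candidate_graph,
    graph_compare,
    join_components,
    prune_by_distance,
)

from conftest import make_anchor, make_gene

# non-periodic 76-nt sequence (periodic ones make substitutions look like shifts
# to the edit metric)
SEQ = "".join(random.Random(42).choice("ACGT") for _ in range(76))


def mutate(seq, n, start=0, step=7):
    """Substitute n positions spaced ``step`` apart starting at ``start``."""
    s = list(seq)
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for k in range(n):
        i = (start + k * step) % len(s)
        s[i] = flip[s[i]]
    return "".join(s)


def cluster_layout(n_b_genes=1, b_positions=None):
    anchors = [
        make_anchor("p", {"A": (0, 100), "B": (0, 100)}),
        make_anchor("q", {"A": (1000, 1100), "B": (1000, 1100)}),
    ]
    genes = [make_gene("A_x", "A", 500, seq=SEQ)]
    positions = b_positions or [300 + 200 * i for i in range(n_b_genes)]
    genes += [make_gene(f"B_y{i}", "B", p, seq=SEQ) for i, p in enumerate(positions)]
    return genes, anchors


class TestCandidateGraph:
    def test_single_edge_between_enclosed_genes(self, two_species_cluster):
        genes, anchors = two_species_cluster
        G = build_candidate_graph(genes, anchors)
        assert G.edges == {frozenset(("A_x", "B_y"))}

    def test_gene_outside_interval_gets_no_edge(self):
        genes, anchors = cluster_layout()
        genes.append(make_gene("B_far", "B", 5000))
        G = build_candidate_graph(genes, anchors)
        assert frozenset(("A_x", "B_far")) not in G.edges

    def test_all_enclosed_loci_become_candidates(self):
        # a query gene gains edges to exactly the loci between its tight anchors
        genes, anchors = cluster_layout(b_positions=[200, 400, 700])
        G = build_candidate_graph(genes, anchors)
        assert {tuple(sorted(e)) for e in G.edges} == {
            ("A_x", "B_y0"), ("A_x", "B_y1"), ("A_x", "B_y2"),
        }

    def test_same_species_genes_share_cluster_but_no_edge(self):
        genes, anchors = cluster_layout(b_positions=[300, 600])
        G = build_candidate_graph(genes, anchors)
        assert G.cluster_of["B_y0"] == G.cluster_of["B_y1"]
        assert frozenset(("B_y0", "B_y1")) not in G.edges

    def test_unanchored_gene_is_flagged_singleton(self):
        genes, anchors = cluster_layout()
        genes.append(make_gene("B_end", "B", 2000))  # beyond the last anchor
        G = build_candidate_graph(genes, anchors)
        assert "B_end" in G.flags
        assert G.cluster_of["B_end"] != G.cluster_of["B_y0"]

    def test_opposite_strand_gene_needs_allow_inversions(self):
        genes, anchors = cluster_layout()
        genes[1] = make_gene("B_y0", "B", 300, strand="-")
        strict = build_candidate_graph(genes, anchors, allow_inversions=False)
        relaxed = build_candidate_graph(genes, anchors, allow_inversions=True)
        assert strict.edges == set()
        assert relaxed.edges == {frozenset(("A_x", "B_y0"))}

    def test_multipartite_at_every_stage(self):
        genes, anchors = cluster_layout(b_positions=[300, 600])
        G = build_candidate_graph(genes, anchors)
        for e in G.edges:
            u, v = tuple(e)
            assert G.species_of(u) != G.species_of(v)


class TestPruneByDistance:
    def test_identical_sequences_kept(self, two_species_cluster):
        genes, anchors = two_species_cluster
        G = prune_by_distance(build_candidate_graph(genes, anchors))
        assert len(G.edges) == 1

    def test_thirteen_percent_divergence_removed(self):
        genes, anchors = cluster_layout()
        genes[1].sequence = mutate(SEQ, 10)  # 10/76 = 13% > 10%
        G = prune_by_distance(build_candidate_graph(genes, anchors))
        assert G.edges == set()

    def test_anticodon_only_difference_kept(self):
        # remolding candidate: 3 of 76 positions (~4%) stay connected
        genes, anchors = cluster_layout()
        genes[1].sequence = mutate(SEQ, 3, start=33, step=1)
        G = prune_by_distance(build_candidate_graph(genes, anchors))
        assert len(G.edges) == 1

    def test_idempotent(self):
        genes, anchors = cluster_layout(b_positions=[300, 600])
        genes[1].sequence = mutate(SEQ, 10)
        G1 = prune_by_distance(build_candidate_graph(genes, anchors))
        G2 = prune_by_distance(G1)
        assert G1.edges == G2.edges

    def test_subset_of_candidate(self):
        genes, anchors = cluster_layout(b_positions=[300, 600])
        genes[2].sequence = mutate(SEQ, 20)
        Gc = build_candidate_graph(genes, anchors)
        Ga = prune_by_distance(Gc)
        assert Ga.edges <= Gc.edges

    def test_missing_sequence_drops_edge(self, two_species_cluster):
        genes, anchors = two_species_cluster
        genes[1].sequence = ""
        G = prune_by_distance(build_candidate_graph(genes, anchors))
        assert G.edges == set()

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            DistanceParams(threshold_fraction=1.5)


class TestJoinComponents:
    def chain_layout(self):
        # three clusters [p|..|q], [q|..|r], [r|..|s] sharing consecutive boundaries
        anchors = [
            make_anchor(a, {"A": (i * 1000, i * 1000 + 100), "B": (i * 1000, i * 1000 + 100)})
            for i, a in enumerate(["p", "q", "r", "s"])
        ]
        genes = []
        for i, sp_pos in enumerate([500, 1500, 2500]):
            genes.append(make_gene(f"A_g{i}", "A", sp_pos))
            genes.append(make_gene(f"B_g{i}", "B", sp_pos))
        return genes, anchors

    def test_shared_boundary_merges_clusters(self):
        genes, anchors = self.chain_layout()
        G = build_candidate_graph(genes, anchors)
        assert len(G.clusters) == 3
        J = join_components(G)
        assert len(J.clusters) == 1  # transitive closure over shared boundaries

    def test_edges_unchanged_components_non_increasing(self):
        genes, anchors = self.chain_layout()
        G = build_candidate_graph(genes, anchors)
        J = join_components(G)
        assert J.edges == G.edges
        assert len(J.components()) <= len(G.components())

    def test_disjoint_boundaries_unchanged(self):
        anchors = [
            make_anchor("p", {"A": (0, 100), "B": (0, 100)}),
            make_anchor("q", {"A": (1000, 1100), "B": (1000, 1100)}),
            make_anchor("r", {"A": (5000, 5100), "B": (5000, 5100)}),
            make_anchor("s", {"A": (6000, 6100), "B": (6000, 6100)}),
        ]
        genes = [make_gene("A_1", "A", 500), make_gene("B_1", "B", 500),
                 make_gene("A_2", "A", 5500), make_gene("B_2", "B", 5500)]
        G = build_candidate_graph(genes, anchors)
        J = join_components(G)
        assert len(J.clusters) == len(G.clusters) == 2


class TestGraphCompare:
    def test_identical_graphs(self, two_species_cluster):
        genes, anchors = two_species_cluster
        G = build_candidate_graph(genes, anchors)
        d = graph_compare(G, G)
        assert d["only_g1"] == d["only_g2"] == set()

    def test_symmetric_difference_matches_set_oracle(self):
        rng = random.Random(5)
        genes, anchors = cluster_layout(b_positions=[200, 400, 600, 800])
        G1 = build_candidate_graph(genes, anchors)
        G2 = G1.copy_as("pruned")
        for e in list(G2.g.edges):
            if rng.random() < 0.5:
                G2.g.remove_edge(*e)
        d = graph_compare(G1, G2)
        e1, e2 = G1.edges, G2.edges
        assert d["shared"] == e1 & e2
        assert d["only_g1"] == e1 - e2
        assert d["only_g2"] == e2 - e1
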