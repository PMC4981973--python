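"""Synteny anchors: MAF cleaning, 1:1 protein filtering, tight pairs, interpolation."""

from __future__ import annotations

import random

import pytest

from synterna.anchors import (
    AnchorIndex,
    clean_maf_blocks,
    filter_protein_orthologs,
    interpolate_point,
    interpolate_position,
    interpolation_orthologs,
    tight_anchor_pair,
)
from synterna.intervals import AnchorStatus, ChainBlock, GenomicInterval

from conftest import make_anchor, make_gene


def iv(sp, s, e, chrom="chr1", strand="+"):
    return GenomicInterval(sp, chrom, s, e, strand)


class TestCleanMafBlocks:
    def test_overlapping_blocks_and_trna_dropped(self):
        # B and C overlap each other -> both dropped; only A survives the
        # tRNA-free, overlap-free filter (oracle: pairwise interval sweep)
        blocks = [
            [iv("a", 0, 10), iv("b", 0, 10)],
            [iv("a", 20, 30), iv("b", 20, 30)],
            [iv("a", 25, 35), iv("b", 40, 50)],
        ]
        out = clean_maf_blocks(blocks, [iv("a", 12, 16)])
        assert len(out) == 1
        assert out[0].placements["a"].start == 0

    def test_trna_overlap_excludes_block(self):
        blocks = [[iv("a", 0, 10), iv("b", 0, 10)]]
        assert clean_maf_blocks(blocks, [iv("a", 5, 8)]) == []

    def test_empty_input(self):
        assert clean_maf_blocks([], []) == []

    def test_disjoint_blocks_all_kept(self):
        blocks = [
            [iv("a", 0, 10), iv("b", 0, 10)],
            [iv("a", 50, 60), iv("b", 50, 60)],
        ]
        assert len(clean_maf_blocks(blocks, [])) == 2

    def test_output_pairwise_disjoint_random(self):
        # property: retained blocks never overlap, in any species
        rng = random.Random(7)
        blocks = []
        for _ in range(60):
            s = rng.randrange(0, 500)
            blocks.append([iv("a", s, s + rng.randrange(5, 30)),
                           iv("b", s, s + rng.randrange(5, 30))])
        out = clean_maf_blocks(blocks, [])
        for sp in ("a", "b"):
            ivs = sorted(a.placements[sp] for a in out)
            for x, y in zip(ivs, ivs[1:]):
                assert x.end <= y.start

    def test_duplicate_species_block_rejected(self):
        blocks = [[iv("a", 0, 10), iv("a", 20, 30), iv("b", 0, 10)]]
        assert clean_maf_blocks(blocks, []) == []


class TestFilterProteinOrthologs:
    CHAIN = ChainBlock(iv("a", 0, 1000), iv("b", 0, 1000))

    def test_pair_inside_chain_retained(self):
        out = filter_protein_orthologs([(iv("a", 100, 200), iv("b", 300, 400))], [self.CHAIN])
        assert len(out) == 1

    def test_pair_without_chain_dropped(self):
        pair = (iv("a", 100, 200), iv("b", 3000, 4000))
        assert filter_protein_orthologs([pair], [self.CHAIN]) == []

    def test_many_to_many_resolved_to_one_to_one(self):
        a = iv("a", 100, 200)
        b1, b2 = iv("b", 300, 400), iv("b", 2000, 2100)
        out = filter_protein_orthologs([(a, b1), (a, b2)], [self.CHAIN])
        # chain covers only (a, b1); the surviving set is 1:1
        assert len(out) == 1
        assert out[0].placements["b"].start == 300

    def test_ambiguous_after_chain_filter_dropped_entirely(self):
        a = iv("a", 100, 200)
        b1, b2 = iv("b", 300, 400), iv("b", 500, 600)
        assert filter_protein_orthologs([(a, b1), (a, b2)], [self.CHAIN]) == []


class TestTightAnchorPair:
    def anchors(self):
        return [
            make_anchor("p1", {"a": (0, 20), "b": (0, 20)}),
            make_anchor("p2", {"a": (40, 45)}),  # not placed in b -> skipped
            make_anchor("p3", {"a": (80, 100), "b": (80, 100)}),
        ]

    def test_skips_anchors_missing_in_target(self):
        gene = iv("a", 50, 60)
        pair = tight_anchor_pair(gene, "b", self.anchors())
        assert pair.usable
        assert pair.left.id == "p1" and pair.right.id == "p3"

    def test_missing_right_side(self):
        gene = iv("a", 200, 210)
        pair = tight_anchor_pair(gene, "b", self.anchors())
        assert pair.status is AnchorStatus.MISSING

    def test_split_when_flanks_on_different_target_chroms(self):
        anchors = [
            make_anchor("L", {"a": (0, 10), "b": ("chr1", 0, 10, "+")}),
            make_anchor("R", {"a": (100, 110), "b": ("chr2", 0, 10, "+")}),
        ]
        pair = tight_anchor_pair(iv("a", 50, 60), "b", anchors)
        assert pair.status is AnchorStatus.SPLIT

    def test_matches_linear_scan_oracle_random(self):
        rng = random.Random(3)
        anchors = []
        for i in range(30):
            s = i * 50
            placements = {"a": (s, s + 10)}
            if rng.random() < 0.6:
                placements["b"] = (s, s + 10)
            anchors.append(make_anchor(f"A{i}", placements))
        index = AnchorIndex(anchors)
        for _ in range(50):
            g = rng.randrange(0, 1500)
            gene = iv("a", g, g + 5)
            pair = tight_anchor_pair(gene, "b", index)
            shared = [a for a in anchors if "b" in a.placements]
            lefts = [a for a in shared if a.placements["a"].end <= gene.start]
            rights = [a for a in shared if a.placements["a"].start >= gene.end]
            exp_left = max(lefts, key=lambda a: a.placements["a"].start) if lefts else None
            exp_right = min(rights, key=lambda a: a.placements["a"].start) if rights else None
            assert (pair.left.id if pair.left else None) == (exp_left.id if exp_left else None)
            assert (pair.right.id if pair.right else None) == (exp_right.id if exp_right else None)

    def test_monotone_adding_anchors_never_widens(self):
        gene = iv("a", 50, 60)
        base = self.anchors()
        pair0 = tight_anchor_pair(gene, "b", base)
        extra = base + [make_anchor("p4", {"a": (70, 75), "b": (70, 75)})]
        pair1 = tight_anchor_pair(gene, "b", extra)
        assert pair1.left.placements["a"].start >= pair0.left.placements["a"].start
        assert pair1.right.placements["a"].end <= pair0.right.placements["a"].end


class TestInterpolation:
    def test_worked_example(self):
        # offsets scaled by (q_b - p_b + 1)/(q_a - p_a + 1)
        t = interpolate_point(1500, 1000, 2000, 500, 1000)
        assert t == pytest.approx(500 + (501 / 1001) * 500, abs=1e-9)

    def test_identity_between_identical_genomes(self):
        for x in (0, 123, 999):
            assert interpolate_point(x, 0, 1000, 0, 1000) == pytest.approx(x)

    def test_zero_offset_lands_on_left_anchor(self):
        assert interpolate_point(1000, 1000, 2000, 500, 1000) == 500

    def test_affine_map_recovered_within_one_base(self):
        # if b = alpha*a + beta between the anchors, |t* - b(t_a)| <= 1
        alpha, beta = 0.5, 200
        p_a, q_a = 1000, 3000
        p_b, q_b = alpha * p_a + beta, alpha * q_a + beta
        for t_a in range(1000, 3001, 137):
            t = interpolate_point(t_a, p_a, q_a, p_b, q_b)
            assert abs(t - (alpha * t_a + beta)) <= 1

    def test_corrupt_anchors_raise(self):
        with pytest.raises(ValueError):
            interpolate_point(10, 100, 100, 0, 50)

    def test_both_ends_interpolated(self):
        anchors = [
            make_anchor("L", {"a": (0, 100), "b": (0, 100)}),
            make_anchor("R", {"a": (1000, 1100), "b": (1000, 1100)}),
        ]
        gene = iv("a", 400, 480)
        pair = tight_anchor_pair(gene, "b", anchors)
        t5, t3 = interpolate_position(gene, pair)
        assert t5 == pytest.approx(400, abs=1)
        assert t3 == pytest.approx(480, abs=1)


class TestInterpolationOrthologs:
    def layout(self, genes_b_starts):
        anchors = [
            make_anchor("L", {"a": (0, 100), "b": (0, 100)}),
            make_anchor("R", {"a": (1000, 1100), "b": (1000, 1100)}),
        ]
        genes_a = [make_gene("a1", "a", 500)]
        genes_b = [make_gene(f"b{i}", "b", s) for i, s in enumerate(genes_b_starts, 1)]
        return genes_a, genes_b, anchors

    def test_symmetric_single_pair(self):
        ga, gb, anchors = self.layout([500])
        assert interpolation_orthologs(ga, gb, anchors) == [("a1", "b1")]

    def test_deleted_target_yields_no_pair(self):
        ga, gb, anchors = self.layout([])
        assert interpolation_orthologs(ga, gb, anchors) == []

    def test_tandem_copies_give_single_pair_not_coorthology(self):
        # only the copy closer to the interpolated point is proposed
        ga, gb, anchors = self.layout([480, 700])
        pairs = interpolation_orthologs(ga, gb, anchors)
        assert pairs == [("a1", "b1")]

    def test_partial_matching(self):
        ga, gb, anchors = self.layout([400, 600])
        ga.append(make_gene("a2", "a", 620))
        pairs = interpolation_orthologs(ga, gb, anchors)
        used = [g for p in pairs for g in p]
        assert len(used) == len(set(used))  # each gene in at most one pair
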