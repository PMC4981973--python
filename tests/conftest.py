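"""Shared fixtures and small generators used across the suite."""

from __future__ import annotations

import random

import networkx as nx
import pytest

from synterna.cograph import PARALLEL, SERIES, Cotree
from synterna.genes import TRNAGene
from synterna.intervals import Anchor, GenomicInterval


def make_gene(gid, species, start, seq="ACGT" * 19, anticodon="AGT", strand="+",
              chrom="chr1", pseudo=False, introns=()):
    return TRNAGene(
        id=gid,
        locus=GenomicInterval(species, chrom, start, start + len(seq), strand),
        sequence=seq,
        anticodon=anticodon,
        pseudogene=pseudo,
        introns=list(introns),
    )


def make_anchor(aid, placements):
    """placements: {species: (start, end)} or {species: (chrom, start, end, strand)}."""
    pl = {}
    for sp, spec in placements.items():
        if len(spec) == 2:
            pl[sp] = GenomicInterval(sp, "chr1", spec[0], spec[1])
        else:
            chrom, s, e, strand = spec
            pl[sp] = GenomicInterval(sp, chrom, s, e, strand)
    return Anchor(id=aid, placements=pl)


def random_cotree(rng: random.Random, leaves: list[str], root_label=None) -> Cotree:
    """Random canonical cotree over the given leaves (alternating labels)."""
    if len(leaves) == 1:
        return Cotree(leaf=leaves[0])
    label = root_label or rng.choice([SERIES, PARALLEL])
    k = rng.randint(2, min(len(leaves), 4))
    # partition leaves into k nonempty groups
    shuffled = leaves[:]
    rng.shuffle(shuffled)
    cuts = sorted(rng.sample(range(1, len(leaves)), k - 1)) if k > 1 else []
    groups, prev = [], 0
    for c in cuts + [len(leaves)]:
        groups.append(shuffled[prev:c])
        prev = c
    child_label = PARALLEL if label == SERIES else SERIES
    children = [random_cotree(rng, g, root_label=child_label) for g in groups]
    children.sort(key=lambda t: sorted(t.leaves()))
    return Cotree(label=label, children=children)


def random_newick(rng: random.Random, leaves: list[str]) -> str:
    """Random rooted binary topology with unit-ish branch lengths."""

    def rec(group: list[str]) -> str:
        if len(group) == 1:
            return f"{group[0]}:{rng.randint(1, 3)}"
        cut = rng.randint(1, len(group) - 1)
        return f"({rec(group[:cut])},{rec(group[cut:])}):{rng.randint(1, 3)}"

    inner = rec(leaves)
    return f"({inner});" if not inner.startswith("(") else inner + ";"


@pytest.fixture
def two_species_cluster():
    """One cluster: two anchors shared by A and B, one similar gene each."""
    anchors = [
        make_anchor("p", {"A": (0, 100), "B": (0, 100)}),
        make_anchor("q", {"A": (1000, 1100), "B": (1000, 1100)}),
    ]
    genes = [
        make_gene("A_x", "A", 500),
        make_gene("B_y", "B", 500),
    ]
    return genes, anchors
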