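"""From raw alignment blocks or protein ortholog tables to synteny anchors.

Anchors must be unique (no overlap with any other block) and must not
touch a gene of interest, so that each one pins down a single orthologous
position in every species carrying it.  Tight anchor pairs — the nearest
anchors flanking a query gene that are also placed in a target species —
delimit the candidate orthologs of the gene in that species.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .intervals import Anchor, AnchorPair, AnchorStatus, ChainBlock, GenomicInterval

log = logging.getLogger(__name__)


def clean_maf_blocks(
    blocks: Sequence[Sequence[GenomicInterval]],
    trna_loci: Sequence[GenomicInterval],
) -> list[Anchor]:
    """Filter alignment blocks down to usable anchors.

    A block survives only if, in every species, it overlaps neither a
    tRNA locus nor any other block (retained *or* discarded) — mutual
    overlaps disqualify both parties, since either could be the
    duplicated copy.  Blocks listing two intervals for one species are
    rejected up front with a warning.
    """
    usable: list[tuple[int, dict[str, GenomicInterval]]] = []
    for idx, ivs in enumerate(blocks):
        per_species: dict[str, GenomicInterval] = {}
        ok = True
        for iv in ivs:
            if iv.species in per_species:
                log.warning("block %d has multiple intervals for %s; rejected", idx, iv.species)
                ok = False
                break
            per_species[iv.species] = iv
        if ok and len(per_species) >= 2:
            usable.append((idx, per_species))

    trna_by_key: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
    for t in trna_loci:
        trna_by_key[(t.species, t.chrom)].append(t)

    bad: set[int] = set()
    # tRNA overlap
    for idx, per_species in usable:
        for iv in per_species.values():
            if any(iv.overlaps(t) for t in trna_by_key.get((iv.species, iv.chrom), ())):
                bad.add(idx)
                break
    # block-block overlap, per species, by coordinate sweep
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = defaultdict(list)
    for idx, per_species in usable:
        for iv in per_species.values():
            by_key[(iv.species, iv.chrom)].append((iv.start, iv.end, idx))
    for ivs_sorted in by_key.values():
        ivs_sorted.sort()
        for (s1, e1, i1), (s2, e2, i2) in zip(ivs_sorted, ivs_sorted[1:]):
            if s2 < e1:
                bad.add(i1)
                bad.add(i2)

    anchors = []
    for idx, per_species in usable:
        if idx in bad:
            continue
        anchors.append(Anchor(id=f"a{idx:05d}", placements=per_species))
    anchors.sort(key=lambda a: min(a.placements.values()))
    return anchors


def filter_protein_orthologs(
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    chains: Sequence[ChainBlock],
) -> list[Anchor]:
    """Resolve many-to-many protein orthologs into 1:1 anchors via chains.

    A pair is kept iff some chain block contains both members; genes that
    then still take part in more than one retained pair are dropped
    entirely, leaving a strict 1:1 anchor set.
    """
    kept: list[tuple[GenomicInterval, GenomicInterval]] = []
    for ga, gb in pairs:
        if any(c.contains_pair(ga, gb) for c in chains):
            kept.append((ga, gb))

    count_a = Counter(ga for ga, _ in kept)
    count_b = Counter(gb for _, gb in kept)
    anchors = []
    n = 0
    for ga, gb in kept:
        if count_a[ga] > 1 or count_b[gb] > 1:
            continue
        anchors.append(Anchor(id=f"p{n:05d}", placements={ga.species: ga, gb.species: gb}))
        n += 1
    return anchors


class AnchorIndex:
    """Sorted per-(species, chromosome) view of an anchor set.

    For each species pair, anchors placed in both species are checked
    for orientation consistency: the relative strand must match the
    majority relative strand of the pair's anchors on that chromosome
    combination; deviating anchors are dropped for that pair (and
    logged), since their order is not comparable between the genomes.
    """

    def __init__(self, anchors: Iterable[Anchor]):
        self.anchors = list(anchors)
        self._by_key: dict[tuple[str, str], list[Anchor]] = defaultdict(list)
        for a in self.anchors:
            for sp, iv in a.placements.items():
                self._by_key[(sp, iv.chrom)].append(a)
        for key in self._by_key:
            self._by_key[key].sort(key=lambda a, k=key: a.placements[k[0]].start)
        self._pair_cache: dict[tuple[str, str, str], tuple[list[int], list[Anchor]]] = {}

    def anchors_on(self, species: str, chrom: str) -> list[Anchor]:
        return self._by_key.get((species, chrom), [])

    def _pair_anchors(self, species: str, chrom: str, target: str) -> tuple[list[int], list[Anchor]]:
        """Anchors on (species, chrom) also placed in ``target``, orientation-filtered."""
        key = (species, chrom, target)
        if key not in self._pair_cache:
            shared = [a for a in self.anchors_on(species, chrom) if target in a.placements]
            groups: dict[str, list[Anchor]] = defaultdict(list)
            for a in shared:
                groups[a.placements[target].chrom].append(a)
            filtered: list[Anchor] = []
            for grp in groups.values():
                majority = Counter(a.relative_strand(species, target) for a in grp).most_common(1)[0][0]
                for a in grp:
                    if a.relative_strand(species, target) == majority:
                        filtered.append(a)
                    else:
                        log.warning(
                            "anchor %s dropped for pair (%s,%s): inconsistent orientation",
                            a.id, species, target,
                        )
            filtered.sort(key=lambda a: a.placements[species].start)
            self._pair_cache[key] = ([a.placements[species].start for a in filtered], filtered)
        return self._pair_cache[key]

    def tight_pair(self, gene: GenomicInterval, target: str, gene_id: str = "") -> AnchorPair:
        return tight_anchor_pair(gene, target, self, gene_id=gene_id)


def tight_anchor_pair(
    gene: GenomicInterval,
    target: str,
    anchors: AnchorIndex | Sequence[Anchor],
    gene_id: str = "",
) -> AnchorPair:
    """Nearest anchors flanking ``gene`` that are also placed in ``target``.

    Anchors not placed in the target species are skipped over, so the
    pair is minimal with respect to the query/target species pair.  A
    side with no such anchor is MISSING; flanks landing on different
    target chromosomes yield SPLIT (treated as missing downstream).
    """
    index = anchors if isinstance(anchors, AnchorIndex) else AnchorIndex(anchors)
    starts, shared = index._pair_anchors(gene.species, gene.chrom, target)

    # left flank: last anchor ending at or before the gene start
    left = None
    i = bisect_right(starts, gene.start) - 1
    while i >= 0:
        if shared[i].placements[gene.species].end <= gene.start:
            left = shared[i]
            break
        i -= 1
    # right flank: first anchor starting at or after the gene end
    right = None
    j = bisect_left(starts, gene.end)
    # bisect by start may land us before anchors overlapping the gene; walk forward
    while j < len(shared) and shared[j].placements[gene.species].start < gene.end:
        j += 1
    if j < len(shared):
        right = shared[j]

    status = AnchorStatus.OK
    if left is None or right is None:
        status = AnchorStatus.MISSING
    elif left.placements[target].chrom != right.placements[target].chrom:
        status = AnchorStatus.SPLIT
    return AnchorPair(query_gene=gene_id, target_species=target, left=left, right=right, status=status)


def interpolate_point(t_a: float, p_a: float, q_a: float, p_b: float, q_b: float) -> float:
    """Map a query coordinate through the affine map defined by two anchor points.

    The gene's offset from the left anchor is scaled by the ratio of the
    inter-anchor sequence lengths:  t* = p_b + (q_b - p_b + 1)/(q_a - p_a + 1) * (t_a - p_a).
    Reproduces the identity when the two coordinate systems coincide.
    """
    span_a = q_a - p_a
    span_b = q_b - p_b
    if span_a <= 0 or span_b <= 0:
        raise ValueError("zero or negative inter-anchor span: corrupt anchors")
    return p_b + (span_b + 1) / (span_a + 1) * (t_a - p_a)


def interpolate_position(gene: GenomicInterval, pair: AnchorPair) -> tuple[float, float]:
    """Interpolated target coordinates of the gene's 5' and 3' ends.

    Uses the inner edges of the tight anchors as anchor points.  Returns
    (start*, end*) in forward-strand coordinates of the target species.
    """
    if not pair.usable:
        raise ValueError("cannot interpolate through a MISSING/SPLIT anchor pair")
    qs, ts = gene.species, pair.target_species
    p_a = pair.left.placements[qs].end
    q_a = pair.right.placements[qs].start
    p_b = pair.left.placements[ts].end
    q_b = pair.right.placements[ts].start
    return (
        interpolate_point(gene.start, p_a, q_a, p_b, q_b),
        interpolate_point(gene.end, p_a, q_a, p_b, q_b),
    )


def _propose(
    genes_q: Sequence, genes_t: Sequence, index: AnchorIndex, k_anchors: int
) -> dict[str, str]:
    """One direction of interpolation-based ortholog proposal."""
    proposals: dict[str, str] = {}
    for g in genes_q:
        target_sp = genes_t[0].locus.species if genes_t else None
        if target_sp is None:
            break
        _, shared = index._pair_anchors(g.locus.species, g.locus.chrom, target_sp)
        if k_anchors and len(shared) > k_anchors:
            shared = sorted(
                shared,
                key=lambda a: abs(a.placements[g.locus.species].midpoint - g.locus.midpoint),
            )[:k_anchors]
            shared.sort(key=lambda a: a.placements[g.locus.species].start)
        sub = AnchorIndex(shared)
        pair = tight_anchor_pair(g.locus, target_sp, sub, gene_id=g.id)
        if not pair.usable:
            continue
        t5, t3 = interpolate_position(g.locus, pair)
        chrom_t = pair.left.placements[target_sp].chrom
        cands = [t for t in genes_t if t.locus.chrom == chrom_t]
        if not cands:
            continue

        def nearest(point: float):
            best = min(abs(t.locus.midpoint - point) for t in cands)
            tied = [t for t in cands if abs(t.locus.midpoint - point) == best]
            # tie → prefer the gene 5' of the interpolated point
            return min(tied, key=lambda t: t.locus.start)

        n5, n3 = nearest(t5), nearest(t3)
        if n5.id != n3.id:
            log.warning("gene %s: 5'/3' interpolations disagree (%s vs %s); dropped", g.id, n5.id, n3.id)
            continue
        proposals[g.id] = n5.id
    return proposals


def interpolation_orthologs(
    genes_a: Sequence,
    genes_b: Sequence,
    anchors: Iterable[Anchor],
    k_proteins: int = 10,
) -> list[tuple[str, str]]:
    """Reciprocal-nearest 1:1 orthologs by linear coordinate interpolation.

    For each query gene the ``k_proteins`` closest usable anchors define
    the tight pair; the gene's 5' and 3' ends are mapped into the target
    and the nearest target gene is proposed.  Only reciprocally proposed
    pairs are returned.  This route cannot produce co-orthologs: of two
    tandem copies only the one nearer the interpolated point is matched.
    """
    index = AnchorIndex(anchors)
    fwd = _propose(genes_a, genes_b, index, k_proteins)
    rev = _propose(genes_b, genes_a, index, k_proteins)
    return sorted((ga, gb) for ga, gb in fwd.items() if rev.get(gb) == ga)
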