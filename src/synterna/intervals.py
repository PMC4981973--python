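"""Genomic intervals, synteny anchors, and tight anchor pairs.

All coordinates are 0-based half-open on the forward strand; strand is
carried separately.  An *anchor* is a uniquely aligned interval placed in
two or more species whose placements are 1:1 orthologous — the positional
landmarks from which synteny is read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


@dataclass(frozen=True, order=True)
class GenomicInterval:
    species: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.species}:{self.chrom}:{self.start}-{self.end}"
            )
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.species == other.species
            and self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class Anchor:
    """A set of 1:1-orthologous loci, one placement per species."""

    id: str
    placements: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, iv in self.placements.items():
            if iv.species != sp:
                raise ValueError(f"anchor {self.id}: placement species mismatch for {sp}")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.placements)

    def relative_strand(self, a: str, b: str) -> str:
        """'+' if the anchor reads in the same direction in both species."""
        return "+" if self.placements[a].strand == self.placements[b].strand else "-"


class AnchorStatus(Enum):
    OK = "OK"
    MISSING = "MISSING"  # no flanking anchor on at least one side
    SPLIT = "SPLIT"      # flanks resolve to different target chromosomes


@dataclass
class AnchorPair:
    """Tight anchors flanking a query gene with respect to one target species.

    ``left``/``right`` are the nearest anchors (in the query species) on
    either side of the gene that are also placed in the target species.
    A side without such an anchor is ``None`` and the pair is flagged
    MISSING; flanks on different target chromosomes are flagged SPLIT.
    """

    query_gene: str
    target_species: str
    left: Anchor | None
    right: Anchor | None
    status: AnchorStatus = AnchorStatus.OK

    def __post_init__(self) -> None:
        if self.status is AnchorStatus.OK and (self.left is None or self.right is None):
            self.status = AnchorStatus.MISSING

    @property
    def usable(self) -> bool:
        return self.status is AnchorStatus.OK


@dataclass(frozen=True)
class ChainBlock:
    """One aligned interval pair from a pairwise alignment chain."""

    interval_a: GenomicInterval
    interval_b: GenomicInterval

    def contains_pair(self, locus_a: GenomicInterval, locus_b: GenomicInterval) -> bool:
        return (
            self.interval_a.chrom == locus_a.chrom
            and self.interval_b.chrom == locus_b.chrom
            and self.interval_a.start <= locus_a.start
            and locus_a.end <= self.interval_a.end
            and self.interval_b.start <= locus_b.start
            and locus_b.end <= self.interval_b.end
        )
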