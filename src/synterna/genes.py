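"""tRNA gene records, the genetic code, and sequence dissimilarity.

Genes annotated on a genome are the vertices of every homology graph in
this package.  Because tRNA paralogs evolve concertedly (gene conversion
keeps copies near-identical within a species), sequence distance is used
only as a coarse family discriminator, never as a phylogenetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval

# Standard genetic code, codon -> one-letter amino acid ('*' = stop).
# Kept as an explicit literal so the mapping is auditable and has no
# runtime dependency; tests cross-check it against an external table.
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# One-letter -> three-letter amino acid names as printed by tRNAscan-SE.
AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Sup",
}
THREE_TO_ONE = {v: k for k, v in AA_THREE.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_to_codon(anticodon: str) -> str:
    """The codon read by a tRNA is the reverse complement of its anticodon."""
    ac = anticodon.upper()
    if len(ac) != 3 or any(c not in "ACGT" for c in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    return reverse_complement(ac)


def anticodon_to_aa(anticodon: str) -> str:
    """One-letter amino acid decoded by an anticodon ('*' for suppressor/stop)."""
    return GENETIC_CODE[anticodon_to_codon(anticodon)]


def isoacceptor_class(anticodon: str) -> str:
    """Three-letter isoacceptor family name for an anticodon."""
    return AA_THREE[anticodon_to_aa(anticodon)]


@dataclass
class TRNAGene:
    """An annotated tRNA locus.

    ``introns`` holds (start, end) pairs relative to the gene's 5' end,
    half-open.  ``isoacceptor`` is derived from the anticodon under the
    standard genetic code; pseudogenes without a callable anticodon carry
    ``"Undet"``.
    """

    id: str
    locus: GenomicInterval
    sequence: str
    anticodon: str
    isoacceptor: str = ""
    pseudogene: bool = False
    introns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.isoacceptor:
            try:
                self.isoacceptor = isoacceptor_class(self.anticodon)
            except (ValueError, KeyError):
                self.isoacceptor = "Undet"

    @property
    def species(self) -> str:
        return self.locus.species

    @property
    def has_intron(self) -> bool:
        return bool(self.introns)


def hamming_distance(s1: str, s2: str) -> int:
    if len(s1) != len(s2):
        raise ValueError("Hamming distance undefined for unequal lengths")
    return sum(a != b for a, b in zip(s1, s2))


def edit_distance(s1: str, s2: str) -> int:
    """Levenshtein distance (unit costs); O(len1*len2), fine for tRNA-sized inputs."""
    if s1 == s2:
        return 0
    if len(s1) < len(s2):
        s1, s2 = s2, s1
    prev = list(range(len(s2) + 1))
    for i, a in enumerate(s1, 1):
        cur = [i]
        for j, b in enumerate(s2, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


def normalized_distance(s1: str, s2: str, metric: str = "edit") -> float:
    """Sequence dissimilarity on [0, ~1].

    ``edit``: Levenshtein distance over the mean length (defined for
    unequal lengths).  ``hamming``: classical Hamming over the common
    length; raises for unequal lengths.
    """
    if not s1 or not s2:
        raise ValueError("empty sequence")
    if metric == "hamming":
        return hamming_distance(s1.upper(), s2.upper()) / len(s1)
    if metric == "edit":
        return edit_distance(s1.upper(), s2.upper()) / ((len(s1) + len(s2)) / 2)
    raise ValueError(f"unknown metric {metric!r}")
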