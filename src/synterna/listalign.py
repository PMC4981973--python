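"""Duplication-aware alignment of ordered gene lists.

Within a synteny cluster the genes of two species are compared as ordered
lists (not nucleotide sequences).  A generalized Needleman-Wunsch allows,
besides matches and gaps, 1:q / q:1 columns that model local tandem
duplications: the q copies are each scored like a match against the
single partner, plus an extra per-copy duplication penalty.  The scoring
is dominated by excluding dissimilar genes from matching at all
(dissimilar pairs score infinity), so the precise finite constants matter
little for tRNA-sized problems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .genes import normalized_distance
from .graph import OrthologyGraph

log = logging.getLogger(__name__)

INF = math.inf


@dataclass
class ScoringParams:
    """Costs for the generalized list alignment.

    match_cost applies between similar genes (normalized distance below
    ``similarity_threshold``); dissimilar genes can never be matched
    (infinite cost).  The defaults satisfy
    ``match_cost < 2 * gap_cost`` (similar genes prefer matching over a
    double gap) and ``2 * match_cost + duplication_penalty <
    match_cost + gap_cost`` (a duplication of similar genes beats
    match-plus-gap).
    """

    match_cost: float = 20.0
    gap_cost: float = 25.0
    duplication_penalty: float = 3.0
    similarity_threshold: float = 0.10
    q_max: int = 2
    metric: str = "edit"

    def __post_init__(self) -> None:
        if self.duplication_penalty <= 0:
            raise ValueError("duplication_penalty must be > 0")
        if not self.match_cost < 2 * self.gap_cost:
            raise ValueError("need match_cost < 2 * gap_cost")
        if not 2 * self.match_cost + self.duplication_penalty < self.match_cost + self.gap_cost:
            raise ValueError("need 2*match_cost + duplication_penalty < match_cost + gap_cost")
        if self.q_max < 1:
            raise ValueError("q_max must be >= 1")


@dataclass(frozen=True)
class Column:
    """One alignment column; ``a_genes``/``b_genes`` may be empty (gap) or
    hold several genes (duplication side)."""

    kind: str  # match | gap_a | gap_b | dup_a | dup_b
    a_genes: tuple[str, ...]
    b_genes: tuple[str, ...]
    cost: float


@dataclass
class AlignmentResult:
    columns: list[Column]
    cost: float
    species_a: str = ""
    species_b: str = ""
    cluster_id: str = ""

    @property
    def match_edges(self) -> set[frozenset[str]]:
        """Orthology edges implied by the alignment: match columns plus the
        complete bipartite graph of every duplication column."""
        out: set[frozenset[str]] = set()
        for col in self.columns:
            for ga in col.a_genes:
                for gb in col.b_genes:
                    out.add(frozenset((ga, gb)))
        return out


def make_delta(sequences: dict[str, str], params: ScoringParams) -> Callable[[str, str], float]:
    """Pairwise gene dissimilarity: fixed cost for similar genes, infinite
    for genes above the similarity threshold (they may never be matched)."""
    cache: dict[frozenset[str], float] = {}

    def delta(x: str, y: str) -> float:
        key = frozenset((x, y))
        if key not in cache:
            d = normalized_distance(sequences[x], sequences[y], params.metric)
            cache[key] = params.match_cost if d < params.similarity_threshold else INF
        return cache[key]

    return delta


def align_lists(
    la: Sequence[str],
    lb: Sequence[str],
    params: ScoringParams,
    sequences: dict[str, str],
    delta: Callable[[str, str], float] | None = None,
) -> AlignmentResult:
    """Optimal generalized alignment of two ordered gene lists.

    DP over prefixes with transitions: match, gap in either list, and
    1:q / q:1 duplication columns for q up to ``params.q_max``.  The
    traceback is deterministic: on cost ties the case order is
    match > dup(1:q) > dup(q:1) > gap-in-a > gap-in-b, smaller q first.
    """
    delta = delta or make_delta(sequences, params)
    gap = params.gap_cost
    eta = params.duplication_penalty
    n, m = len(la), len(lb)

    D = [[INF] * (m + 1) for _ in range(n + 1)]
    ptr: list[list[tuple | None]] = [[None] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = D[i - 1][0] + gap
        ptr[i][0] = ("gap_a", 1, 0)
    for j in range(1, m + 1):
        D[0][j] = D[0][j - 1] + gap
        ptr[0][j] = ("gap_b", 0, 1)

    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            candidates: list[tuple[float, tuple]] = []
            if i >= 1 and j >= 1:
                candidates.append((D[i - 1][j - 1] + delta(la[i - 1], lb[j - 1]), ("match", 1, 1)))
            # 1:q — one gene of a vs q consecutive genes of b
            for q in range(2, params.q_max + 1):
                if i >= 1 and j >= q:
                    cost = D[i - 1][j - q] + (q - 1) * eta
                    for k in range(q):
                        cost += delta(la[i - 1], lb[j - 1 - k])
                    candidates.append((cost, ("dup_b", 1, q)))
                if j >= 1 and i >= q:
                    cost = D[i - q][j - 1] + (q - 1) * eta
                    for k in range(q):
                        cost += delta(la[i - 1 - k], lb[j - 1])
                    candidates.append((cost, ("dup_a", q, 1)))
            if i >= 1:
                candidates.append((D[i - 1][j] + gap, ("gap_a", 1, 0)))
            if j >= 1:
                candidates.append((D[i][j - 1] + gap, ("gap_b", 0, 1)))

            best, move = INF, None
            for cost, mv in candidates:
                if cost < best:
                    best, move = cost, mv
            D[i][j] = best
            ptr[i][j] = move

    # traceback
    columns: list[Column] = []
    i, j = n, m
    while i > 0 or j > 0:
        kind, di, dj = ptr[i][j]
        a_part = tuple(la[i - di:i])
        b_part = tuple(lb[j - dj:j])
        col_cost = D[i][j] - D[i - di][j - dj]
        columns.append(Column(kind, a_part, b_part, col_cost))
        i, j = i - di, j - dj
    columns.reverse()
    return AlignmentResult(columns=columns, cost=D[n][m])


def build_estimated_orthology(
    G_pruned: OrthologyGraph,
    alignments: Sequence[AlignmentResult],
) -> OrthologyGraph:
    """Superimpose all pairwise list alignments into the estimated
    orthology graph.

    Match columns contribute their edge; a 1:q duplication column
    contributes the complete bipartite graph from the single gene to all
    q copies.  Any proposed edge absent from the pruned graph signals a
    scoring/threshold mismatch and is dropped with a warning.
    """
    out = G_pruned.copy_as("estimated")
    out.g.remove_edges_from(list(out.g.edges))
    allowed = G_pruned.edges
    for aln in alignments:
        for edge in aln.match_edges:
            if edge in allowed:
                u, v = tuple(edge)
                out.add_edge(u, v)
            else:
                log.warning("alignment edge %s not present in pruned graph; dropped", set(edge))
    return out
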