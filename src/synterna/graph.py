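"""Staged homology graphs over tRNA loci.

The candidate graph connects genes of different species that lie between
each other's tight anchors; distance pruning then removes edges between
clearly distinct sequences (different isoacceptor families); the list
alignment stage (see ``listalign``) thins this further to the estimated
orthology relation.  Each stage is a spanning subgraph of the previous
one.  Genes between the same pair of tight anchors form a *synteny
cluster*, which also groups same-species copies that can never share an
edge.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .anchors import AnchorIndex
from .genes import TRNAGene, normalized_distance
from .intervals import Anchor, AnchorStatus

log = logging.getLogger(__name__)

STAGES = ("candidate", "pruned", "estimated", "edited")


@dataclass
class DistanceParams:
    """Sequence-distance pruning parameters.

    ``threshold_fraction`` is the upper bound on divergence within the
    phylogenetic range of interest: edges between genes whose normalized
    distance reaches it are cut.  Default 0.10 (10 % of the gene length).
    """

    threshold_fraction: float = 0.10
    metric: str = "edit"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")


@dataclass
class Cluster:
    id: str
    members: set[str] = field(default_factory=set)
    boundaries: set[str] = field(default_factory=set)  # anchor ids delimiting the cluster


class OrthologyGraph:
    """A homology graph over annotated genes, at one refinement stage."""

    def __init__(self, genes: dict[str, TRNAGene], stage: str = "candidate"):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.genes = genes
        self.stage = stage
        self.g = nx.Graph()
        self.g.add_nodes_from(genes)
        self.cluster_of: dict[str, str] = {}
        self.clusters: dict[str, Cluster] = {}
        self.flags: dict[str, str] = {}  # gene -> reason code (MISSING_ANCHOR, SPLIT, ...)

    # -- basic accessors -------------------------------------------------
    def species_of(self, gene_id: str) -> str:
        return self.genes[gene_id].species

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.g.edges}

    def add_edge(self, u: str, v: str) -> None:
        if self.species_of(u) == self.species_of(v):
            raise ValueError(f"same-species edge {u}-{v} not allowed")
        self.g.add_edge(u, v)

    def copy_as(self, stage: str) -> "OrthologyGraph":
        out = OrthologyGraph(self.genes, stage)
        out.g = self.g.copy()
        out.cluster_of = dict(self.cluster_of)
        out.clusters = {
            cid: Cluster(cid, set(c.members), set(c.boundaries)) for cid, c in self.clusters.items()
        }
        out.flags = dict(self.flags)
        return out

    # -- clusters --------------------------------------------------------
    def _assign_clusters(self, assignment: dict[str, str], boundaries: dict[str, set[str]]) -> None:
        self.cluster_of = dict(assignment)
        self.clusters = {}
        for gid, cid in assignment.items():
            self.clusters.setdefault(cid, Cluster(cid)).members.add(gid)
        for cid, bnd in boundaries.items():
            if cid in self.clusters:
                self.clusters[cid].boundaries |= bnd

    def gene_list(self, cluster_id: str, species: str) -> list[str]:
        """Cluster members of one species ordered by coordinate (both strands)."""
        members = [g for g in self.clusters[cluster_id].members if self.species_of(g) == species]
        members.sort(key=lambda g: (self.genes[g].locus.chrom, self.genes[g].locus.start))
        return members

    def cluster_species(self, cluster_id: str) -> set[str]:
        return {self.species_of(g) for g in self.clusters[cluster_id].members}

    # -- components ------------------------------------------------------
    def components(self, link_clusters: bool = True) -> list[set[str]]:
        """Connected components over edges plus same-cluster co-membership."""
        h = self.g.copy()
        if link_clusters:
            for c in self.clusters.values():
                members = sorted(c.members)
                h.add_edges_from(zip(members, members[1:]))
        return [set(c) for c in nx.connected_components(h)]

    def event_components(self, params: DistanceParams | None = None) -> list[set[str]]:
        """Components for event accounting.

        Same-species co-cluster genes are joined into a component only
        when their sequences are similar (same family); dissimilar
        families sharing a synteny cluster stay separate co-ortholog
        groups.
        """
        params = params or DistanceParams()
        h = self.g.copy()
        for c in self.clusters.values():
            per_sp: dict[str, list[str]] = defaultdict(list)
            for gid in c.members:
                per_sp[self.species_of(gid)].append(gid)
            for members in per_sp.values():
                for i, u in enumerate(members):
                    for v in members[i + 1:]:
                        su, sv = self.genes[u].sequence, self.genes[v].sequence
                        if not su or not sv:
                            continue
                        if normalized_distance(su, sv, params.metric) < params.threshold_fraction:
                            h.add_edge(u, v)
        return [set(c) for c in nx.connected_components(h)]


def build_candidate_graph(
    genes: list[TRNAGene],
    anchors: list[Anchor],
    allow_inversions: bool = False,
) -> OrthologyGraph:
    """Candidate graph: an edge wherever two genes of different species
    lie between each other's tight anchors.

    Genes whose tight anchor pair is MISSING or SPLIT for a species pair
    get no edges for that pair and are flagged; genes unplaceable toward
    every other species become singleton clusters excluded from cluster
    analysis.  Without ``allow_inversions`` the genes' relative strand
    must match the anchors' relative orientation.
    """
    gene_map = {g.id: g for g in genes}
    graph = OrthologyGraph(gene_map, "candidate")
    index = AnchorIndex(anchors)
    species = sorted({g.species for g in genes})
    by_sp: dict[str, list[TRNAGene]] = defaultdict(list)
    for g in genes:
        by_sp[g.species].append(g)
    for sp in by_sp:
        by_sp[sp].sort(key=lambda g: (g.locus.chrom, g.locus.start))

    # tight pairs per (gene, target species)
    pairs: dict[tuple[str, str], object] = {}
    for g in genes:
        for target in species:
            if target == g.species:
                continue
            p = index.tight_pair(g.locus, target, gene_id=g.id)
            pairs[(g.id, target)] = p
            if p.status is not AnchorStatus.OK:
                graph.flags.setdefault(g.id, f"{p.status.value}_ANCHOR")

    # candidate sets per direction
    def enclosed(gid: str, target: str) -> set[str]:
        p = pairs[(gid, target)]
        if not p.usable:
            return set()
        g = gene_map[gid]
        lo = p.left.placements[target]
        hi = p.right.placements[target]
        if lo.start > hi.start:  # inverted relative orientation
            lo, hi = hi, lo
        rel = p.left.relative_strand(g.species, target)
        out = set()
        cands = by_sp.get(target, [])
        starts = [(c.locus.chrom, c.locus.start) for c in cands]
        i = bisect_left(starts, (lo.chrom, lo.end))
        while i < len(cands) and cands[i].locus.chrom == lo.chrom and cands[i].locus.end <= hi.start:
            t = cands[i]
            strand_ok = (t.locus.strand == g.locus.strand) == (rel == "+")
            if strand_ok or allow_inversions:
                out.add(t.id)
            i += 1
        return out

    for a_i, sp_a in enumerate(species):
        for sp_b in species[a_i + 1:]:
            fwd = {g.id: enclosed(g.id, sp_b) for g in by_sp[sp_a]}
            rev = {g.id: enclosed(g.id, sp_a) for g in by_sp[sp_b]}
            for ga, cands in fwd.items():
                for gb in cands:
                    if ga in rev.get(gb, ()):
                        graph.add_edge(ga, gb)

    # synteny clusters: genes sharing a tight-anchor interval, via union-find
    parent: dict[str, str] = {g.id: g.id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    bucket: dict[frozenset[str], list[str]] = defaultdict(list)
    gene_bounds: dict[str, set[str]] = defaultdict(set)
    for (gid, _target), p in pairs.items():
        if p.usable:
            key = frozenset((p.left.id, p.right.id))
            bucket[key].append(gid)
            gene_bounds[gid] |= {p.left.id, p.right.id}
    for members in bucket.values():
        for other in members[1:]:
            union(members[0], other)

    roots: dict[str, str] = {}
    assignment: dict[str, str] = {}
    boundaries: dict[str, set[str]] = defaultdict(set)
    n = 0
    for g in sorted(gene_map):
        r = find(g)
        if r not in roots:
            roots[r] = f"c{n:05d}"
            n += 1
        cid = roots[r]
        assignment[g] = cid
        boundaries[cid] |= gene_bounds.get(g, set())
    graph._assign_clusters(assignment, boundaries)
    return graph


def prune_by_distance(G: OrthologyGraph, params: DistanceParams | None = None) -> OrthologyGraph:
    """Cut candidate edges between clearly distinct sequences.

    Anticodon identity is deliberately *not* required: a remolded gene
    differs from its orthologs essentially only in the anticodon and must
    stay connected.  Idempotent.
    """
    params = params or DistanceParams()
    out = G.copy_as("pruned")
    for u, v in list(out.g.edges):
        su, sv = G.genes[u].sequence, G.genes[v].sequence
        if not su or not sv:
            log.warning("edge %s-%s dropped: missing sequence", u, v)
            out.g.remove_edge(u, v)
            continue
        if normalized_distance(su, sv, params.metric) >= params.threshold_fraction:
            out.g.remove_edge(u, v)
    return out


def join_components(G: OrthologyGraph) -> OrthologyGraph:
    """Merge synteny clusters that share a boundary anchor.

    Corresponds to coarsening the synteny definition: adjacent alignment
    blocks delimit one larger syntenic region.  Edges are untouched; the
    number of connected components can only go down.
    """
    out = G.copy_as(G.stage)
    cids = sorted(out.clusters)
    parent = {c: c for c in cids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    owner: dict[str, str] = {}
    for cid in cids:
        for b in sorted(out.clusters[cid].boundaries):
            if b in owner:
                ra, rb = find(owner[b]), find(cid)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            else:
                owner[b] = cid

    merged: dict[str, Cluster] = {}
    assignment: dict[str, str] = {}
    for cid in cids:
        root = find(cid)
        tgt = merged.setdefault(root, Cluster(root))
        tgt.members |= out.clusters[cid].members
        tgt.boundaries |= out.clusters[cid].boundaries
        for gid in out.clusters[cid].members:
            assignment[gid] = root
    out.clusters = merged
    out.cluster_of = assignment
    return out


def graph_compare(G1: OrthologyGraph, G2: OrthologyGraph) -> dict[str, set[frozenset[str]]]:
    """Symmetric-difference comparison of two orthology estimates."""
    e1, e2 = G1.edges, G2.edges
    return {"shared": e1 & e2, "only_g1": e1 - e2, "only_g2": e2 - e1}
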