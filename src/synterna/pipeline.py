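"""The stepwise refinement pipeline: anchors → Γc → Γa → Γo → cographs → events.

Each stage is an ordinary function over the library types; ``reconstruct``
chains them, and ``run_pipeline`` adds file I/O around it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cograph import Cotree, edit_to_cograph, EditSet
from .events import (
    ComponentSummary,
    EventTable,
    SpeciesTree,
    intron_consistency,
    summarize_events,
)
from .genes import TRNAGene
from .graph import (
    DistanceParams,
    OrthologyGraph,
    build_candidate_graph,
    graph_compare,
    join_components,
    prune_by_distance,
)
from .intervals import Anchor
from .listalign import AlignmentResult, ScoringParams, align_lists, build_estimated_orthology, make_delta

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Fully defaulted pipeline configuration (YAML-loadable)."""

    anchor_source: str = "simulated"  # maf | proteins | simulated
    scoring: ScoringParams = field(default_factory=ScoringParams)
    distance: DistanceParams = field(default_factory=DistanceParams)
    join_clusters: bool = False
    allow_inversions: bool = False
    lineage_exception: bool = False
    exception_pairs: list[list[str]] = field(default_factory=list)
    exact_cograph_bound: int = 10
    k_proteins: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        scoring = ScoringParams(**data.pop("scoring", {}))
        distance = DistanceParams(**data.pop("distance", {}))
        return cls(scoring=scoring, distance=distance, **data)

    def to_dict(self) -> dict:
        return {
            "anchor_source": self.anchor_source,
            "scoring": vars(self.scoring),
            "distance": vars(self.distance),
            "join_clusters": self.join_clusters,
            "allow_inversions": self.allow_inversions,
            "lineage_exception": self.lineage_exception,
            "exception_pairs": self.exception_pairs,
            "exact_cograph_bound": self.exact_cograph_bound,
            "k_proteins": self.k_proteins,
            "seed": self.seed,
        }


@dataclass
class Artifacts:
    graph_candidate: OrthologyGraph
    graph_pruned: OrthologyGraph
    graph_estimated: OrthologyGraph
    graph_edited: OrthologyGraph
    alignments: list[AlignmentResult]
    edits: list[EditSet]
    cotrees: dict[str, Cotree]
    event_table: EventTable
    components: list[ComponentSummary]
    intron_violations: list[str]
    intron_ranges: dict[str, tuple[int, int]]


def align_clusters(
    G_pruned: OrthologyGraph,
    params: ScoringParams,
) -> list[AlignmentResult]:
    """All pairwise generalized list alignments, one per species pair per
    multi-species synteny cluster."""
    sequences = {gid: g.sequence for gid, g in G_pruned.genes.items()}
    delta = make_delta(sequences, params)
    out: list[AlignmentResult] = []
    for cid in sorted(G_pruned.clusters):
        species = sorted(G_pruned.cluster_species(cid))
        if len(species) < 2:
            continue
        for i, sa in enumerate(species):
            for sb in species[i + 1:]:
                la = G_pruned.gene_list(cid, sa)
                lb = G_pruned.gene_list(cid, sb)
                if not la or not lb:
                    continue
                aln = align_lists(la, lb, params, sequences, delta=delta)
                aln.species_a, aln.species_b, aln.cluster_id = sa, sb, cid
                out.append(aln)
    return out


def edit_components(
    G_estimated: OrthologyGraph,
    exact_bound: int = 10,
) -> tuple[OrthologyGraph, list[EditSet]]:
    """Edit every connected component of the estimated graph to the nearest
    cograph (components are independent)."""
    import networkx as nx

    out = G_estimated.copy_as("edited")
    species_of = {gid: G_estimated.species_of(gid) for gid in G_estimated.genes}
    edits: list[EditSet] = []
    for comp in sorted(nx.connected_components(G_estimated.g), key=sorted):
        if len(comp) < 4:
            continue
        sub = G_estimated.g.subgraph(comp).copy()
        edit = edit_to_cograph(sub, exact_bound=exact_bound, species_of=species_of)
        if edit.size == 0:
            continue
        edits.append(edit)
        for e in edit.deletions:
            out.g.remove_edge(*tuple(e))
        for e in edit.insertions:
            u, v = tuple(e)
            if species_of[u] == species_of[v]:
                log.warning("edit wants same-species edge %s-%s; skipped", u, v)
                continue
            out.g.add_edge(u, v)
    return out, edits


def reconstruct(
    genes: list[TRNAGene],
    anchors: list[Anchor],
    tree: SpeciesTree,
    config: PipelineConfig | None = None,
) -> Artifacts:
    """Run the full refinement chain on annotated genes and anchors."""
    cfg = config or PipelineConfig()
    gc = build_candidate_graph(genes, anchors, allow_inversions=cfg.allow_inversions)
    if cfg.join_clusters:
        gc = join_components(gc)
    ga = prune_by_distance(gc, cfg.distance)
    alignments = align_clusters(ga, cfg.scoring)
    go = build_estimated_orthology(ga, alignments)
    ge, edits = edit_components(go, exact_bound=cfg.exact_cograph_bound)
    exception_pairs = {frozenset(p) for p in cfg.exception_pairs} or None
    table, summaries = summarize_events(
        ge, tree,
        dist_params=cfg.distance,
        lineage_exception=cfg.lineage_exception,
        exception_pairs=exception_pairs,
        exact_bound=cfg.exact_cograph_bound,
    )
    cotrees = {s.id: s.cotree for s in summaries if s.cotree is not None}
    comp_members = {s.id: s.members for s in summaries}
    violations, ranges = intron_consistency(comp_members, ge.genes)
    return Artifacts(
        graph_candidate=gc, graph_pruned=ga, graph_estimated=go, graph_edited=ge,
        alignments=alignments, edits=edits, cotrees=cotrees,
        event_table=table, components=summaries,
        intron_violations=violations, intron_ranges=ranges,
    )


def check_invariants(art: Artifacts) -> None:
    """Stage-chain and multipartiteness invariants; raises on violation."""
    ec = art.graph_candidate.edges
    ea = art.graph_pruned.edges
    eo = art.graph_estimated.edges
    if not ea <= ec:
        raise AssertionError("pruned edges not a subset of candidate edges")
    if not eo <= ea:
        raise AssertionError("estimated edges not a subset of pruned edges")
    for G in (art.graph_candidate, art.graph_pruned, art.graph_estimated, art.graph_edited):
        for e in G.edges:
            u, v = tuple(e)
            if G.species_of(u) == G.species_of(v):
                raise AssertionError(f"same-species edge {u}-{v} at stage {G.stage}")


def run_pipeline(
    genes: list[TRNAGene],
    anchors: list[Anchor],
    tree: SpeciesTree,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> Artifacts:
    """``reconstruct`` plus artifact files and the resolved-config log."""
    from . import io as sio

    cfg = config or PipelineConfig()
    log.info("resolved config: %s", cfg.to_dict())
    art = reconstruct(genes, anchors, tree, cfg)
    check_invariants(art)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
        with open(out / "anchors.tsv", "w") as fh:
            sio.write_anchors_tsv(fh, anchors)
        with open(out / "genes.tsv", "w") as fh:
            sio.write_genes_tsv(fh, genes)
        for G in (art.graph_candidate, art.graph_pruned, art.graph_estimated, art.graph_edited):
            with open(out / f"graph_{G.stage}.tsv", "w") as fh:
                sio.write_graph_tsv(fh, G)
        with open(out / "clusters.tsv", "w") as fh:
            sio.write_clusters_tsv(fh, art.graph_candidate)
        with open(out / "alignments.tsv", "w") as fh:
            fh.write("cluster_id\tspecies_a\tspecies_b\tkind\ta_genes\tb_genes\tcost\n")
            for aln in art.alignments:
                for col in aln.columns:
                    fh.write(
                        f"{aln.cluster_id}\t{aln.species_a}\t{aln.species_b}\t{col.kind}\t"
                        f"{','.join(col.a_genes)}\t{','.join(col.b_genes)}\t{col.cost}\n"
                    )
        with open(out / "edits.tsv", "w") as fh:
            fh.write("op\tgene_a\tgene_b\toptimal\tnote\n")
            for edit in art.edits:
                for op, pairs in (("insert", edit.insertions), ("delete", edit.deletions)):
                    for pair in sorted(pairs, key=sorted):
                        u, v = sorted(pair)
                        fh.write(f"{op}\t{u}\t{v}\t{int(edit.optimal)}\t{edit.note}\n")
        with open(out / "cotrees.nwk", "w") as fh:
            for cid, t in sorted(art.cotrees.items()):
                fh.write(f"{cid}\t{t.to_newick()}\n")
        with open(out / "events.tsv", "w") as fh:
            fh.write("branch\tgains_seeding\tduplications\ttotal_gain\tlosses\n")
            for row in art.event_table.to_rows():
                fh.write(
                    f"{row['branch']}\t{row['gains_seeding']}\t{row['duplications']}\t"
                    f"{row['total_gain']}\t{row['losses']}\n"
                )
        with open(out / "remoldings.tsv", "w") as fh:
            fh.write("component\tbranch\tsource\ttarget\tclass\tambiguous\n")
            for ev in art.event_table.remoldings:
                fh.write(f"{ev.component}\t{ev.branch}\t{ev.source}\t{ev.target}\t{ev.cls}\t{int(ev.ambiguous)}\n")
        with open(out / "introns.tsv", "w") as fh:
            fh.write("component\tstatus\tmin_len\tmax_len\n")
            for cid in art.intron_violations:
                fh.write(f"{cid}\tVIOLATION\t\t\n")
            for cid, (lo, hi) in sorted(art.intron_ranges.items()):
                fh.write(f"{cid}\tCONSISTENT\t{lo}\t{hi}\n")
    return art


__all__ = [
    "PipelineConfig", "Artifacts", "reconstruct", "run_pipeline",
    "align_clusters", "edit_components", "check_invariants", "graph_compare",
]
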