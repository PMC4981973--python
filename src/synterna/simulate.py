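"""Forward simulation of tRNA cluster evolution with known ground truth.

Gene clusters evolve along a rooted species tree by single-gene tandem
duplication, loss, seeding of new loci, anticodon remolding and
pseudogenization; synteny anchors evolve only by loss.  Concerted
evolution is modeled phenomenologically: every copy of a family is
resampled from the lineage's family consensus with a little noise, so
paralogs stay near-identical within a species — exactly the property
that defeats sequence-based orthology and that this pipeline is built
around.  Coordinates are laid out with fixed spacers, which keeps the
anchor-interpolation map exactly affine when no indel events occur.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .events import SpeciesTree, classify_remolding, dollo_events
from .genes import TRNAGene
from .graph import OrthologyGraph
from .intervals import Anchor, GenomicInterval

DEFAULT_TREE = "(((((Hsa:1,Ptr:1):1,Ggo:2):1,Pab:3):1,Nle:4):1,Mmu:5);"

BASES = "ACGT"
ANTICODON_SLOT = (33, 36)  # anticodon occupies sequence positions 33..35
GENE_LENGTH = 73
SENSE_ANTICODONS = [
    ac for ac in
    ("".join((a, b, c)) for a in BASES for b in BASES for c in BASES)
    if ac not in ("TTA", "TCA", "CTA")  # reverse complements of stop codons
]


@dataclass
class SimConfig:
    """A stated world: a small primate-like clade of clustered tRNA genes.

    Rates are per gene (or per anchor) per unit branch length, except
    ``seeding_rate`` which is per unit branch length genome-wide.  The
    defaults describe genuinely low turnover: over the default tree
    (total length 20) with ~30 gene lineages they give an expectation of
    roughly five duplications, five losses, six seedings and two
    remoldings per replicate — every event type is exercised while most
    components stay clean cliques, which is the regime in which
    order-based orthology is meant to operate.  Families are kept
    internally near-identical (``copy_noise`` expected substitutions per
    realized copy against the lineage consensus) to emulate concerted
    evolution.
    """

    newick: str = DEFAULT_TREE
    duplication_rate: float = 0.008
    loss_rate: float = 0.008
    seeding_rate: float = 0.3
    remolding_rate: float = 0.004
    pseudogenization_rate: float = 0.004
    anchor_loss_rate: float = 0.0
    substitution_rate: float = 0.002  # per site per unit length, consensus drift
    copy_noise: float = 0.5           # expected substitutions per realized copy
    n_families: int = 20
    copies_per_family: tuple[int, ...] = ()  # default: every 3rd family has 2 copies
    intron_fraction: float = 0.2
    intron_length: int = 15
    anchors_per_gap: int = 1
    spacer: int = 400
    anchor_length: int = 200
    seed: int = 0

    def layout(self) -> list[tuple[str, int]]:
        if self.copies_per_family:
            counts = self.copies_per_family
        else:
            counts = tuple(2 if i % 3 == 0 else 1 for i in range(self.n_families))
        return [(f"fam{i:02d}", c) for i, c in enumerate(counts)]


@dataclass
class SimEvent:
    branch: str
    kind: str  # duplication | loss | seeding | remolding | pseudogenization | anchor_loss
    gene: str | None = None
    parent: str | None = None
    source: str | None = None
    target: str | None = None
    seq_no: int = 0


@dataclass
class GroundTruth:
    """What actually happened, in reconstruction-comparable form."""

    edges: set[frozenset[str]]                    # true cross-species orthology
    components: dict[str, set[str]]               # founder lineage -> extant instance ids
    event_log: list[SimEvent]
    gains: dict[str, int]                         # observable, LCA convention
    duplications: dict[str, int]
    losses: dict[str, int]
    remoldings: list[tuple[str, str, str, str]]   # (branch, source, target, class), surviving
    genealogy: dict[str, str | None]              # gene id -> parent gene id
    birth_node: dict[str, str]
    families: dict[str, str] = None               # extant instance id -> family


@dataclass
class SimResult:
    genes: list[TRNAGene]
    anchors: list[Anchor]
    truth: GroundTruth
    tree: SpeciesTree
    config: SimConfig


class _Sim:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = SpeciesTree.from_newick(config.newick)
        self.gene_counter = 0
        self.anchor_counter = 0
        self.seq_no = 0
        self.parent: dict[str, str | None] = {}
        self.birth: dict[str, str] = {}
        self.birth_seq: dict[str, int] = {}
        self.family_of: dict[str, str] = {}
        self.anticodon: dict[str, str] = {}
        self.children_of: dict[str, list[str]] = defaultdict(list)
        self.events: list[SimEvent] = []
        self.leaf_genomes: dict[str, list[tuple[str, str]]] = {}
        self.leaf_gene_state: dict[str, dict[str, dict]] = {}
        self.leaf_consensus: dict[str, dict[str, str]] = {}
        self.family_intron: dict[str, int] = {}  # family -> intron length (0 = none)

    # -- helpers ---------------------------------------------------------
    def _new_gene(self, family: str, anticodon: str, parent: str | None, node: str) -> str:
        gid = f"g{self.gene_counter:05d}"
        self.gene_counter += 1
        self.seq_no += 1
        self.parent[gid] = parent
        self.birth[gid] = node
        self.birth_seq[gid] = self.seq_no
        self.family_of[gid] = family
        self.anticodon[gid] = anticodon
        if parent is not None:
            self.children_of[parent].append(gid)
        return gid

    def _random_seq(self, length: int) -> str:
        return "".join(self.rng.choice(list(BASES), size=length))

    def _new_family(self, name: str) -> tuple[str, str]:
        """Returns (anticodon, consensus sequence with anticodon embedded)."""
        ac = SENSE_ANTICODONS[self.rng.integers(len(SENSE_ANTICODONS))]
        intron = self.cfg.intron_length if self.rng.random() < self.cfg.intron_fraction else 0
        seq = list(self._random_seq(GENE_LENGTH + intron))
        seq[ANTICODON_SLOT[0]:ANTICODON_SLOT[1]] = ac
        self.family_intron[name] = intron
        return ac, "".join(seq)

    def _mutate(self, seq: str, n: int) -> str:
        s = list(seq)
        positions = [i for i in range(len(s)) if not (ANTICODON_SLOT[0] <= i < ANTICODON_SLOT[1])]
        for _ in range(n):
            i = positions[self.rng.integers(len(positions))]
            s[i] = self.rng.choice([b for b in BASES if b != s[i]])
        return "".join(s)

    # -- evolution -------------------------------------------------------
    def run(self) -> SimResult:
        cfg = self.cfg
        # root genome: [anchors] fam block [anchors] fam block ... [anchors]
        genome: list[tuple[str, str]] = []
        consensus: dict[str, str] = {}
        if cfg.anchors_per_gap < 1:
            raise ValueError("pipeline requires at least one anchor per gap (condition S1)")

        def add_anchors() -> None:
            for _ in range(cfg.anchors_per_gap):
                aid = f"A{self.anchor_counter:05d}"
                self.anchor_counter += 1
                genome.append(("A", aid))

        add_anchors()
        for fam, copies in cfg.layout():
            ac, seq = self._new_family(fam)
            consensus[fam] = seq
            founder = self._new_gene(fam, ac, None, self.tree.root)
            genome.append(("G", founder))
            for _ in range(copies - 1):
                # extra root copies are ancestral tandem duplicates of the
                # founder: observationally indistinguishable from (and thus
                # booked as) duplications on the root edge
                gid = self._new_gene(fam, ac, founder, self.tree.root)
                genome.append(("G", gid))
                self.events.append(
                    SimEvent(self.tree.root, "duplication", gene=gid, parent=founder,
                             seq_no=self.birth_seq[gid])
                )
            add_anchors()

        pseudo: dict[str, bool] = {}
        self._evolve(self.tree.root, genome, dict(consensus), dict(pseudo))
        return self._collect()

    def _evolve(
        self,
        node: str,
        genome: list[tuple[str, str]],
        consensus: dict[str, str],
        pseudo: dict[str, bool],
    ) -> None:
        nd = self.tree.nodes[node]
        if not nd.children:
            sp = nd.taxon or node
            self.leaf_genomes[sp] = list(genome)
            self.leaf_consensus[sp] = dict(consensus)
            self.leaf_gene_state[sp] = {
                gid: {"anticodon": self.anticodon[gid], "pseudo": pseudo.get(gid, False)}
                for kind, gid in genome if kind == "G"
            }
            return
        for child in nd.children:
            g2 = list(genome)
            c2 = dict(consensus)
            p2 = dict(pseudo)
            self._branch_events(child, self.tree.nodes[child].length, g2, c2, p2)
            self._evolve(child, g2, c2, p2)

    def _branch_events(
        self,
        branch: str,
        length: float,
        genome: list[tuple[str, str]],
        consensus: dict[str, str],
        pseudo: dict[str, bool],
    ) -> None:
        cfg = self.cfg
        rng = self.rng

        def gene_positions() -> list[int]:
            return [i for i, (k, _) in enumerate(genome) if k == "G"]

        n_genes = len(gene_positions())
        n_anchors = len(genome) - n_genes
        draws = {
            "duplication": rng.poisson(cfg.duplication_rate * length * n_genes),
            "loss": rng.poisson(cfg.loss_rate * length * n_genes),
            "seeding": rng.poisson(cfg.seeding_rate * length),
            "remolding": rng.poisson(cfg.remolding_rate * length * n_genes),
            "pseudogenization": rng.poisson(cfg.pseudogenization_rate * length * n_genes),
            "anchor_loss": rng.poisson(cfg.anchor_loss_rate * length * n_anchors),
        }
        queue = [k for k, n in draws.items() for _ in range(n)]
        rng.shuffle(queue)

        for kind in queue:
            gp = gene_positions()
            if kind == "duplication" and gp:
                i = gp[rng.integers(len(gp))]
                src = genome[i][1]
                gid = self._new_gene(self.family_of[src], self.anticodon[src], src, branch)
                if pseudo.get(src):
                    pseudo[gid] = True
                genome.insert(i + 1, ("G", gid))
                self.events.append(SimEvent(branch, "duplication", gene=gid, parent=src, seq_no=self.birth_seq[gid]))
            elif kind == "loss" and gp:
                i = gp[rng.integers(len(gp))]
                gid = genome.pop(i)[1]
                self.events.append(SimEvent(branch, "loss", gene=gid))
            elif kind == "seeding":
                fam = f"fam{len(self.family_intron):02d}"
                ac, seq = self._new_family(fam)
                consensus[fam] = seq
                gid = self._new_gene(fam, ac, None, branch)
                # interior position only: a seeded locus must stay anchored on both sides
                pos = int(rng.integers(1, len(genome)))
                genome.insert(pos, ("G", gid))
                self.events.append(SimEvent(branch, "seeding", gene=gid))
            elif kind == "remolding" and gp:
                i = gp[rng.integers(len(gp))]
                gid = genome[i][1]
                old = self.anticodon[gid]
                choices = [a for a in SENSE_ANTICODONS if a != old]
                new = choices[rng.integers(len(choices))]
                # remolding creates a divergent gene state; give it its own id so
                # descendants can be traced, parent = pre-remolding gene
                rid = self._new_gene(self.family_of[gid], new, gid, branch)
                genome[i] = ("G", rid)
                if pseudo.get(gid):
                    pseudo[rid] = True
                self.events.append(
                    SimEvent(branch, "remolding", gene=rid, parent=gid, source=old, target=new)
                )
            elif kind == "pseudogenization" and gp:
                i = gp[rng.integers(len(gp))]
                pseudo[genome[i][1]] = True
                self.events.append(SimEvent(branch, "pseudogenization", gene=genome[i][1]))
            elif kind == "anchor_loss":
                ap = [i for i, (k, _) in enumerate(genome) if k == "A"]
                if len(ap) > 2:
                    i = ap[rng.integers(len(ap))]
                    aid = genome.pop(i)[1]
                    self.events.append(SimEvent(branch, "anchor_loss", gene=aid))

        # consensus drift
        for fam in list(consensus):
            n_mut = rng.poisson(cfg.substitution_rate * length * len(consensus[fam]))
            if n_mut:
                consensus[fam] = self._mutate(consensus[fam], n_mut)

    # -- output assembly -------------------------------------------------
    def _collect(self) -> SimResult:
        cfg = self.cfg
        genes: list[TRNAGene] = []
        anchor_placements: dict[str, dict[str, GenomicInterval]] = defaultdict(dict)
        instance_of: dict[tuple[str, str], str] = {}

        for sp in sorted(self.leaf_genomes):
            pos = 0
            for kind, eid in self.leaf_genomes[sp]:
                pos += cfg.spacer
                if kind == "A":
                    anchor_placements[eid][sp] = GenomicInterval(sp, "chr1", pos, pos + cfg.anchor_length)
                    pos += cfg.anchor_length
                else:
                    fam = self.family_of[eid]
                    state = self.leaf_gene_state[sp][eid]
                    cons = self.leaf_consensus[sp][fam]
                    seq = list(self._mutate(cons, int(self.rng.poisson(cfg.copy_noise))))
                    seq[ANTICODON_SLOT[0]:ANTICODON_SLOT[1]] = state["anticodon"]
                    seq = "".join(seq)
                    iid = f"{sp}_{eid}"
                    instance_of[(sp, eid)] = iid
                    intron = self.family_intron.get(fam, 0)
                    introns = [(38, 38 + intron)] if intron else []
                    genes.append(
                        TRNAGene(
                            id=iid,
                            locus=GenomicInterval(sp, "chr1", pos, pos + len(seq)),
                            sequence=seq,
                            anticodon=state["anticodon"],
                            pseudogene=state["pseudo"],
                            introns=introns,
                        )
                    )
                    pos += len(seq)

        anchors = [
            Anchor(id=aid, placements=pl)
            for aid, pl in sorted(anchor_placements.items())
            if len(pl) >= 2
        ]

        truth = self._ground_truth(instance_of)
        truth.families = {
            iid: self.family_of[gid] for (sp, gid), iid in instance_of.items()
        }
        return SimResult(genes=genes, anchors=anchors, truth=truth, tree=self.tree, config=cfg)

    def _founder(self, gid: str) -> str:
        while self.parent[gid] is not None:
            gid = self.parent[gid]
        return gid

    def _ancestor_at(self, gid: str, node: str, ancestors: dict[str, set[str]]) -> str:
        # climb until the gene's birth node is at or above `node`; a lineage
        # seeded strictly below `node` bottoms out at its founder (which then
        # cannot match any gene of another species)
        while self.birth[gid] not in ancestors[node]:
            p = self.parent[gid]
            if p is None:
                break
            gid = p
        return gid

    def _desc_ids(self, gid: str) -> set[str]:
        out = {gid}
        stack = [gid]
        while stack:
            g = stack.pop()
            for c in self.children_of.get(g, ()):
                out.add(c)
                stack.append(c)
        return out

    def _ground_truth(self, instance_of: dict[tuple[str, str], str]) -> GroundTruth:
        tree = self.tree
        ancestors = {nid: set(tree.path_to_root(nid)) for nid in tree.nodes}
        species = sorted(self.leaf_genomes)
        extant_by_sp: dict[str, set[str]] = {
            sp: {gid for k, gid in self.leaf_genomes[sp] if k == "G"} for sp in species
        }
        extant_ids: set[str] = set().union(*extant_by_sp.values()) if species else set()

        edges: set[frozenset[str]] = set()
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                s = tree.lca({a, b})
                anc_a = {g: self._ancestor_at(g, s, ancestors) for g in extant_by_sp[a]}
                for gb in extant_by_sp[b]:
                    ob = self._ancestor_at(gb, s, ancestors)
                    for ga, oa in anc_a.items():
                        if oa == ob:
                            edges.add(frozenset((instance_of[(a, ga)], instance_of[(b, gb)])))

        # founder components over extant instances
        components: dict[str, set[str]] = defaultdict(set)
        comp_species: dict[str, set[str]] = defaultdict(set)
        for sp in species:
            for gid in extant_by_sp[sp]:
                f = self._founder(gid)
                components[f].add(instance_of[(sp, gid)])
                comp_species[f].add(sp)

        gains: dict[str, int] = defaultdict(int)
        losses: dict[str, int] = defaultdict(int)
        duplications: dict[str, int] = defaultdict(int)
        gain_branch_of_founder: dict[str, str] = {}
        for f, sps in comp_species.items():
            gb, lb = dollo_events(sps, tree)
            gain_branch_of_founder[f] = gb[0]
            for b in gb:
                gains[b] += 1
            for b in lb:
                losses[b] += 1

        # surviving duplications, booked on the component's gain branch
        for ev in self.events:
            if ev.kind != "duplication":
                continue
            f = self._founder(ev.gene)
            if f not in gain_branch_of_founder:
                continue
            below = tree.leafset(ev.branch)
            copy_desc = self._desc_ids(ev.gene)
            copy_alive = any(copy_desc & extant_by_sp[sp] for sp in below)
            parent_side = {ev.parent}
            for sib in self.children_of.get(ev.parent, ()):
                if sib != ev.gene and self.birth_seq[sib] > ev.seq_no:
                    parent_side |= self._desc_ids(sib)
            parent_alive = any(parent_side & extant_by_sp[sp] for sp in below)
            if copy_alive and parent_alive:
                duplications[gain_branch_of_founder[f]] += 1

        # surviving remoldings
        remoldings: list[tuple[str, str, str, str]] = []
        for ev in self.events:
            if ev.kind != "remolding":
                continue
            desc = self._desc_ids(ev.gene)
            alive = any(
                gid in extant_by_sp[sp] and self.anticodon[gid] == ev.target
                for sp in species for gid in desc & extant_by_sp[sp]
            )
            if alive:
                remoldings.append((ev.branch, ev.source, ev.target, classify_remolding(ev.source, ev.target)))

        return GroundTruth(
            edges=edges,
            components={f: ids for f, ids in components.items()},
            event_log=list(self.events),
            gains=dict(gains),
            duplications=dict(duplications),
            losses=dict(losses),
            remoldings=remoldings,
            genealogy=dict(self.parent),
            birth_node=dict(self.birth),
        )


def simulate(config: SimConfig) -> SimResult:
    """Run one forward simulation; identical seeds give identical output."""
    return _Sim(config).run()


def score_reconstruction(
    truth: GroundTruth,
    estimate: OrthologyGraph,
    est_duplications: dict[str, int] | None = None,
    est_remoldings: list | None = None,
) -> dict:
    """Compare a reconstruction with the simulated truth.

    Edge precision/recall/F1 are exact set comparisons; per-branch event
    deltas are signed (estimate minus truth); remolding recovery is the
    fraction of surviving simulated remoldings matched by an inferred
    event with the same source, target and class.
    """
    est_edges = estimate.edges
    tp = len(est_edges & truth.edges)
    precision = tp / len(est_edges) if est_edges else 1.0
    recall = tp / len(truth.edges) if truth.edges else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    out = {
        "edge_precision": precision,
        "edge_recall": recall,
        "edge_f1": f1,
        "n_true_edges": len(truth.edges),
        "n_est_edges": len(est_edges),
    }
    if est_duplications is not None:
        branches = set(truth.duplications) | set(est_duplications)
        out["duplication_deltas"] = {
            b: est_duplications.get(b, 0) - truth.duplications.get(b, 0) for b in sorted(branches)
        }
    if est_remoldings is not None:
        want = defaultdict(int)
        for _, src, tgt, cls in truth.remoldings:
            want[(src, tgt, cls)] += 1
        have = defaultdict(int)
        for ev in est_remoldings:
            have[(ev.source, ev.target, ev.cls)] += 1
        total = sum(want.values())
        hit = sum(min(n, have[k]) for k, n in want.items())
        out["remolding_recovery"] = hit / total if total else 1.0
        out["n_true_remoldings"] = total
    return out
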