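"""Mapping co-ortholog components onto the species tree.

Gains and losses follow Dollo parsimony: a locus (co-ortholog component)
is seeded once, on the edge above the last common ancestor of all species
in which it is observed, and lost independently on the minimal set of
branches that prunes the absent species.  Duplications read off the
cotrees are booked on the gain branch of their component.  Anticodon
remoldings are inferred by parsimony on the component's gene tree and
classified by whether the decoded amino acid changes (iso vs allo).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import dendropy
import networkx as nx

from .cograph import Cotree, cograph_to_cotree, count_duplications, edit_to_cograph, is_cograph
from .genes import TRNAGene, anticodon_to_aa
from .graph import DistanceParams, OrthologyGraph

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# species tree

@dataclass
class TreeNode:
    id: str
    parent: str | None
    children: list[str]
    length: float
    taxon: str | None  # species name on leaves


class SpeciesTree:
    """Rooted species tree; branches are addressed by their child node id
    (leaf branches by the species name)."""

    def __init__(self, nodes: dict[str, TreeNode], root: str):
        self.nodes = nodes
        self.root = root
        self._leafsets: dict[str, frozenset[str]] = {}
        self._fill_leafsets(root)

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        nodes: dict[str, TreeNode] = {}
        counter = [0]

        def node_id(nd) -> str:
            if nd.taxon is not None:
                return nd.taxon.label.replace(" ", "_")
            if nd.label:
                return nd.label
            counter[0] += 1
            nd.label = f"n{counter[0]}"
            return nd.label

        root_id = None
        for nd in dt.preorder_node_iter():
            nid = node_id(nd)
            pid = node_id(nd.parent_node) if nd.parent_node is not None else None
            if pid is None:
                root_id = nid
            nodes[nid] = TreeNode(
                id=nid,
                parent=pid,
                children=[],
                length=nd.edge.length if nd.edge.length is not None else 1.0,
                taxon=nd.taxon.label.replace(" ", "_") if nd.taxon else None,
            )
        for nid, nd in nodes.items():
            if nd.parent is not None:
                nodes[nd.parent].children.append(nid)
        return cls(nodes, root_id)

    def _fill_leafsets(self, nid: str) -> frozenset[str]:
        nd = self.nodes[nid]
        if not nd.children:
            ls = frozenset({nd.taxon or nid})
        else:
            ls = frozenset().union(*(self._fill_leafsets(c) for c in nd.children))
        self._leafsets[nid] = ls
        return ls

    @property
    def leaves(self) -> frozenset[str]:
        return self._leafsets[self.root]

    def leafset(self, nid: str) -> frozenset[str]:
        return self._leafsets[nid]

    def branches(self) -> list[str]:
        return list(self.nodes)

    def lca(self, species: set[str]) -> str:
        missing = set(species) - self.leaves
        if missing:
            raise ValueError(f"species absent from tree: {sorted(missing)}")
        best = self.root
        changed = True
        while changed:
            changed = False
            for c in self.nodes[best].children:
                if species <= self._leafsets[c]:
                    best = c
                    changed = True
                    break
        return best

    def preorder(self, start: str | None = None):
        stack = [start or self.root]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    def path_to_root(self, nid: str) -> list[str]:
        out = [nid]
        while self.nodes[out[-1]].parent is not None:
            out.append(self.nodes[out[-1]].parent)
        return out


# --------------------------------------------------------------------------
# Dollo parsimony

def dollo_events(
    leafset: set[str],
    tree: SpeciesTree,
    lineage_exception: bool = False,
    exception_pairs: set[frozenset[str]] | None = None,
) -> tuple[list[str], list[str]]:
    """Single-gain/minimal-loss placement of a component on the species tree.

    Returns (gain branches, loss branches), branches keyed by child node.
    The gain sits on the edge above the LCA of the observed species;
    losses prune every maximal absent subtree below it.  With
    ``lineage_exception``, a leafset equal to one of the configured
    species pairs is explained as two independent lineage-specific gains
    with no losses (used for patterns like macaque + human only, where a
    deep gain plus many losses is implausible).
    """
    if not leafset:
        raise ValueError("empty leafset")
    missing = set(leafset) - tree.leaves
    if missing:
        raise ValueError(f"species absent from tree: {sorted(missing)}")

    if lineage_exception and exception_pairs and frozenset(leafset) in exception_pairs:
        return sorted(leafset), []

    lca = tree.lca(set(leafset))
    losses: list[str] = []
    for nid in tree.preorder(lca):
        nd = tree.nodes[nid]
        present = bool(tree.leafset(nid) & leafset)
        if not present:
            continue
        for c in nd.children:
            if not (tree.leafset(c) & leafset):
                losses.append(c)
    return [lca], sorted(losses)


# --------------------------------------------------------------------------
# event table

@dataclass
class BranchEvents:
    gains_seeding: int = 0
    duplications: int = 0
    losses: int = 0

    @property
    def total_gain(self) -> int:
        return self.gains_seeding + self.duplications


@dataclass
class RemoldingEvent:
    source: str
    target: str
    cls: str  # iso | allo
    branch: str
    component: str
    ambiguous: bool = False


@dataclass
class EventTable:
    branches: dict[str, BranchEvents] = field(default_factory=lambda: defaultdict(BranchEvents))
    remoldings: list[RemoldingEvent] = field(default_factory=list)
    pseudogenes: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    notes: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "branch": b,
                "gains_seeding": ev.gains_seeding,
                "duplications": ev.duplications,
                "total_gain": ev.total_gain,
                "losses": ev.losses,
            }
            for b, ev in sorted(self.branches.items())
        ]


# --------------------------------------------------------------------------
# remolding

def classify_remolding(ac_from: str, ac_to: str) -> str:
    """'none' if identical, 'iso' if the amino acid is conserved under the
    standard genetic code, 'allo' otherwise."""
    aa_from = anticodon_to_aa(ac_from)  # validates characters
    aa_to = anticodon_to_aa(ac_to)
    if ac_from.upper() == ac_to.upper():
        return "none"
    return "iso" if aa_from == aa_to else "allo"


def _fitch_sets(node: Cotree, states: dict[str, str]) -> dict[int, frozenset[str]]:
    """Bottom-up state sets, generalized to multifurcations by keeping the
    states shared by the largest number of children."""
    sets: dict[int, frozenset[str]] = {}

    def rec(n: Cotree) -> frozenset[str]:
        if n.is_leaf:
            s = frozenset({states[n.leaf]})
        else:
            child_sets = [rec(c) for c in n.children]
            count: dict[str, int] = defaultdict(int)
            for cs in child_sets:
                for st in cs:
                    count[st] += 1
            top = max(count.values())
            s = frozenset(st for st, c in count.items() if c == top)
        sets[id(n)] = s
        return s

    rec(node)
    return sets


def detect_remoldings(
    components: dict[str, tuple[set[str], Cotree]],
    genes: dict[str, TRNAGene],
    tree: SpeciesTree,
) -> list[RemoldingEvent]:
    """Anticodon state changes within co-ortholog components.

    For every component whose members carry at least two distinct
    anticodons, ancestral anticodons are inferred by parsimony on the
    component's cotree (ties resolved toward the parent state, pushing
    changes to shallower branches).  Each change maps to the species-tree
    branch above the LCA of the species under the changed subtree; a
    change at a leaf maps to that species' terminal branch.  Ambiguous
    root states are flagged.
    """
    events: list[RemoldingEvent] = []
    for comp_id, (members, cotree) in sorted(components.items()):
        states = {}
        for gid in members:
            try:
                anticodon_to_aa(genes[gid].anticodon)
            except (ValueError, KeyError):
                continue  # pseudogene without callable anticodon
            states[gid] = genes[gid].anticodon.upper()
        if len(set(states.values())) < 2:
            continue
        pruned = _prune_cotree(cotree, set(states))
        if pruned is None:
            continue
        sets = _fitch_sets(pruned, states)
        root_set = sets[id(pruned)]
        ambiguous_root = len(root_set) > 1
        assigned: dict[int, str] = {}

        def assign(n: Cotree, parent_state: str | None) -> None:
            s = sets[id(n)]
            if parent_state is not None and parent_state in s:
                st = parent_state
            else:
                st = min(s)
            assigned[id(n)] = st
            if parent_state is not None and st != parent_state:
                leaf_species = {genes[g].species for g in n.leaves()}
                if len(leaf_species) > 1:
                    branch = tree.lca(leaf_species)
                else:
                    branch = next(iter(leaf_species))
                events.append(
                    RemoldingEvent(
                        source=parent_state,
                        target=st,
                        cls=classify_remolding(parent_state, st),
                        branch=branch,
                        component=comp_id,
                        ambiguous=ambiguous_root,
                    )
                )
            for c in n.children:
                assign(c, st)

        assign(pruned, None)
    return events


def _prune_cotree(node: Cotree, keep: set[str]) -> Cotree | None:
    """Restrict a cotree to a leaf subset, suppressing unary nodes."""
    if node.is_leaf:
        return node if node.leaf in keep else None
    children = [c for c in (_prune_cotree(ch, keep) for ch in node.children) if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    return Cotree(label=node.label, children=children)


# --------------------------------------------------------------------------
# intron consistency

def intron_consistency(
    components: dict[str, set[str]],
    genes: dict[str, TRNAGene],
) -> tuple[list[str], dict[str, tuple[int, int]]]:
    """Check that within each co-ortholog component either all or none of
    the members carry an intron.

    Returns (violating component ids, intron length range per consistent
    intron-bearing component).
    """
    violating: list[str] = []
    ranges: dict[str, tuple[int, int]] = {}
    for comp_id, members in sorted(components.items()):
        with_intron = [g for g in members if genes[g].has_intron]
        if not with_intron:
            continue
        if len(with_intron) < len(members):
            violating.append(comp_id)
            continue
        lengths = [e - s for g in with_intron for s, e in genes[g].introns]
        ranges[comp_id] = (min(lengths), max(lengths))
    return violating, ranges


# --------------------------------------------------------------------------
# event summary

@dataclass
class ComponentSummary:
    id: str
    members: set[str]
    species: set[str]
    gain_branches: list[str]
    loss_branches: list[str]
    duplications: int
    cotree: Cotree | None
    edit_size: int = 0
    notes: str = ""


def summarize_events(
    G_edited: OrthologyGraph,
    tree: SpeciesTree,
    dist_params: DistanceParams | None = None,
    lineage_exception: bool = False,
    exception_pairs: set[frozenset[str]] | None = None,
    exact_bound: int = 10,
) -> tuple[EventTable, list[ComponentSummary]]:
    """Per-branch gain/duplication/loss accounting over all components.

    Components group orthology edges together with same-species
    co-cluster copies of the same family.  Multi-species components get
    one Dollo gain (or two lineage-specific gains under the configured
    exception) and their cotree duplications on the gain branch;
    single-species components contribute a terminal gain plus one
    duplication per extra copy.
    """
    dist_params = dist_params or DistanceParams()
    table = EventTable()
    summaries: list[ComponentSummary] = []
    comps = sorted(G_edited.event_components(dist_params), key=lambda c: sorted(c))
    species_of = {gid: G_edited.species_of(gid) for gid in G_edited.genes}

    for idx, members in enumerate(comps):
        comp_id = f"comp{idx:05d}"
        sp = {species_of[g] for g in members}
        sub = G_edited.g.subgraph(members).copy()
        notes = ""
        if not is_cograph(sub):
            # should not happen on an edited graph; repair defensively
            edit = edit_to_cograph(sub, exact_bound=exact_bound, species_of=species_of)
            sub = edit.apply(sub)
            notes = f"re-edited ({edit.size} edits)"
        cotree = cograph_to_cotree(sub) if len(members) > 1 else Cotree(leaf=next(iter(members)))
        try:
            dups = count_duplications(cotree, species_of)
        except ValueError as exc:
            dups = count_duplications(cotree, None)
            notes = (notes + "; " if notes else "") + f"orthology violation: {exc}"

        gains, losses = dollo_events(sp, tree, lineage_exception, exception_pairs)
        for b in gains:
            table.branches[b].gains_seeding += 1
        for b in losses:
            table.branches[b].losses += 1
        if dups:
            table.branches[gains[0]].duplications += dups

        for g in members:
            if G_edited.genes[g].pseudogene:
                table.pseudogenes[species_of[g]] += 1

        summaries.append(
            ComponentSummary(
                id=comp_id, members=set(members), species=sp,
                gain_branches=gains, loss_branches=losses,
                duplications=dups, cotree=cotree, notes=notes,
            )
        )

    table.remoldings = detect_remoldings(
        {s.id: (s.members, s.cotree) for s in summaries if s.cotree is not None},
        G_edited.genes,
        tree,
    )
    return table, summaries
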