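# Methods

## The problem

Multicopy gene families under concerted evolution — tRNAs are the model
case — keep their paralogs near-identical within a species through gene
conversion. Sequence similarity therefore carries no information about
which copies in two species descend from the same ancestral locus:
reciprocal-best-hit orthology and gene-tree reconciliation both fail.
What concerted evolution does *not* erase is gene order. `synterna`
reconstructs orthology and duplication/gain/loss/remolding histories
purely from conserved synteny, using uniquely aligned flanking elements
("anchors") as positional landmarks.

## The model and its assumptions

Two structural assumptions underlie everything:

- **(S1)** every gene of interest has anchors on both sides (it is not at
  a contig end), and
- **(S2)** between nearby anchors, genomes evolve only by unduplicated
  vertical inheritance and tandem duplications of single loci — no
  rearrangements, no multi-gene block duplications.

Under (S1)/(S2) the orthologs of a query gene in another species must lie
between the *tight anchors* of that gene: the nearest flanking anchors
that are also placed in the target species. The pipeline is a stepwise
refinement of a homology graph over all annotated genes:

1. **Candidate graph** (`build_candidate_graph`) — an edge wherever two
   genes of different species lie between each other's tight anchors.
   The true orthology relation is a subgraph of this by construction.
   Genes sharing a tight-anchor interval form a *synteny cluster*
   (including conspecific copies, which never receive edges).
2. **Distance pruning** (`prune_by_distance`) — edges between clearly
   distinct sequences are cut (different isoacceptor families sharing a
   cluster). The threshold is an upper bound on within-family divergence
   over the phylogenetic range, default 10 % of the gene length.
   Anticodon identity is deliberately not required, so remolded genes
   stay connected to their orthologs.
3. **List alignment** (`align_lists`) — within each cluster, the ordered
   gene lists of every species pair are aligned with a generalized
   Needleman–Wunsch that adds 1:q / q:1 duplication columns: the q
   copies each pay the match cost against the single partner plus a
   duplication surcharge. Superimposing all pairwise alignments
   (matches plus the complete bipartite graph of each duplication
   column) gives the estimated orthology graph, a spanning subgraph of
   the pruned graph whose components are order-preserving.
4. **Cograph editing** (`edit_to_cograph`) — a valid orthology relation
   contains no induced P4, so each connected component is repaired to
   the nearest cograph (minimum edge insertions + deletions). The
   canonical cotree of the repaired component is the (possibly
   unresolved) gene tree: series nodes are speciations, parallel nodes
   duplications; a parallel node with c children encodes c−1
   duplications.
5. **Event mapping** (`summarize_events`) — each component is placed on
   the species tree by Dollo parsimony: one gain on the edge above the
   LCA of the observed species, losses on the minimal branch set pruning
   the absent ones. Cotree duplications are booked on the gain branch.
   A configurable lineage-exception list replaces implausible
   deep-gain-many-loss explanations for specific two-species patterns
   with two lineage-specific gains.

Anticodon remoldings are inferred per component by parsimony on the
cotree (leaf states = anticodons; multifurcations handled by keeping the
states shared by the most children; ties resolved toward the parent
state, which pushes changes tipward). Each state change maps to the
species-tree branch above the LCA of the species under the changed
subtree and is classified *iso* (same amino acid under the standard
genetic code, anticodon read as the reverse complement codon) or *allo*
(amino acid changes). Intron presence is used as an independent check:
a component in which some members carry an intron and others do not is
flagged.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `DistanceParams.threshold_fraction` | 0.10 | max within-family divergence; 10 % of gene length |
| `DistanceParams.metric` | edit | Levenshtein over mean length; Hamming only for equal lengths |
| `ScoringParams.match_cost` | 20 | cost of matching similar genes (dissimilar = ∞) |
| `ScoringParams.gap_cost` | 25 | unspecified upstream; constrained by match < 2·gap |
| `ScoringParams.duplication_penalty` (η) | 3 | must satisfy 2·match + η < match + gap, so duplications of similar genes beat match+gap |
| `ScoringParams.q_max` | 2 | largest 1:q duplication column |
| `exact_cograph_bound` | 10 vertices | exact minimum editing below, greedy P4-destruction above (flagged) |
| `k_proteins` | 10 | anchors considered per gene in interpolation mode |

The two `ScoringParams` inequalities are enforced at construction; they
are what makes the 1:2 column (cost 2·20+3 = 43) win over match+gap (45)
and the double gap (50) lose to a match (20) for similar genes.

Cograph editing is exact via P4-branching (O(6^k)) with iterative
deepening, seeded by a greedy upper bound and guarded by a search-node
budget; if the budget trips (only possible when a component needs a
large edit set, which already signals upstream noise) the greedy result
is returned flagged non-optimal. Among equal-size optima the tie-break
prefers no conspecific insertions, then more insertions than deletions
(missing edges between pseudogenized pairs are the expected defect),
then lexicographic order; full tie-break enumeration is limited to edit
sizes ≤ 3.

## The synthetic world

`simulate` evolves gene clusters forward along a rooted species tree
(default: a six-species primate-like tree of total length 20). Events
per branch are Poisson draws: single-gene tandem duplication and loss,
seeding of new loci, anticodon remolding, pseudogenization (all per gene
per unit length), and anchor loss (per anchor; default 0). Concerted
evolution is *phenomenological*: every realized copy is resampled from
its lineage's family consensus with ~0.5 expected substitutions, rather
than simulating gene conversion explicitly — the pipeline only relies on
the resulting near-identity of paralogs. Default rates
(duplication/loss 0.008, seeding 0.3/unit, remolding/pseudogenization
0.004) give roughly five duplications, five losses, six seedings and two
remoldings per replicate: genuinely low turnover, the regime order-based
orthology is designed for, while still exercising every event type.
Multi-copy founder families are created as root-edge tandem duplications
of a single founder, because concerted evolution makes independent
same-family seedings and an ancestral tandem duplication observationally
identical — ground truth and reconstruction then share one accounting
convention.

Coordinates are laid out with fixed spacers (gene 73 nt + optional
15 nt intron, anchor 200 nt, spacer 400 nt), which keeps the
anchor-interpolation map exactly affine in indel-free settings and gives
the interpolation code a closed-form check.

What the generator does **not** emulate — and hence what a green
end-to-end test does not establish: genome rearrangements and multi-gene
block duplications (excluded by (S2) itself), assembly artifacts and
alignment noise in anchors, accelerated divergence of pseudogenes (the
flag is inherited but sequences stay family-typical, so the
pseudogene-driven missing-edge/cograph-completion phenomenon seen in
real data does not arise), base-compositional realism, and indels in
gene sequences.

## Numerical and procedural choices

- Coordinates are 0-based half-open on the forward strand everywhere;
  MAF and chain minus-strand records and tRNAscan-SE's 1-based
  begin/end-order encoding are normalized at parse time.
- List-alignment traceback tie-break: match > 1:q > q:1 > gap-in-a >
  gap-in-b, smaller q first — outputs are deterministic.
- Interpolation nearest-gene ties prefer the gene 5' of the interpolated
  point; genes whose 5'- and 3'-end interpolations disagree on the
  nearest target are dropped and logged.
- Anchors whose relative orientation deviates from the majority for a
  species pair are dropped for that pair (order would not be
  comparable); tight-anchor flanks on different target chromosomes are
  flagged SPLIT and treated as missing.
- Dollo gains sit on the edge *above* the LCA; the root edge is
  addressable so pan-species components are "gained before the first
  speciation".
- Event components join orthology edges with conspecific co-cluster
  pairs below the distance threshold; this is what lets single-species
  clusters carry duplication counts (parallel cotree over the copies)
  without ever creating same-species "orthology" edges.
- Remoldings whose source state is extinct within a component are
  unobservable in principle; detection is evaluated against observable
  events only. Ambiguous ancestral states (e.g., an ancient paralog
  pair where polarity cannot be decided) are reported once, flagged, at
  the shallowest consistent branch.

## Known limitations

- Exact cograph editing is exponential in the edit size; components
  above 10 vertices (or beyond the node budget) get a greedy,
  possibly non-minimal repair, and components above 30 vertices are
  left unedited with a diagnostic.
- The list alignment cannot represent non-order-preserving co-orthology
  (e.g., independent duplications in different lineages interleaved by
  losses); with a copy lost, a 1:2 column over-assigns co-orthology by
  construction (cost 43 < 45). These are properties of the method, not
  of the implementation, and bound achievable edge precision/recall as
  turnover grows.
- Fitch on multifurcating cotrees uses the majority-state
  generalization, which is a heuristic for true multifurcation
  parsimony; with the tie-toward-parent rule it is exact on the binary
  case and deterministic everywhere.
- The interpolation route is inherently 1:1 and will not recover
  co-orthologs of tandem duplicates.
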