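# synterna

Synteny-anchored orthology and turnover reconstruction for gene families
evolving under **concerted evolution** — tRNAs being the canonical case.

Paralogous tRNA copies are homogenized by gene conversion and stay
near-identical within a species over long evolutionary times, so sequence
similarity cannot tell orthologs from paralogs: reciprocal best hits and
gene-tree reconciliation are both blind here. What survives is **gene
order**. `synterna` reconstructs orthology — and the duplication, gain,
loss and anticodon-remolding history behind it — from conserved synteny
alone, for researchers studying the turnover of clustered multicopy
genes (tRNAs, and by extension other concertedly evolving families).

## The method in one paragraph

Uniquely aligned flanking elements (genome-alignment blocks or 1:1
orthologous proteins) serve as *anchors* `p ≺ t ≺ q`. The orthologs of a
gene `t^a` in species `b` must lie between the *tight anchors* of `t^a`
into `b` — the nearest flanks also placed in `b`. This yields a candidate
graph Γ_c over all genes (an edge when two genes lie between each other's
tight anchors; the true orthology relation is a subgraph by
construction). Γ_c is pruned to Γ_a by cutting edges between clearly
distinct sequences (normalized distance ≥ 10 %), then refined to the
estimated orthology graph Γ_o by superimposing duplication-aware list
alignments of each synteny cluster: a generalized Needleman–Wunsch

    D_ij = min { D_{i-1,j-1} + δ(t^a_i, t^b_j),          match
                 D_{i-1,j}   + δ(t^a_i, −),              gap
                 D_{i,j-1}   + δ(−, t^b_j),              gap
                 D_{i-1,j-2} + δ(t^a_i,t^b_{j-1}) + δ(t^a_i,t^b_j) + η }   1:2 duplication (and q:1, q ≤ q_max)

with δ = 20 for similar genes, ∞ otherwise, gap 25, η = 3. Because every
valid orthology relation is a **cograph** (P4-free), each component of
Γ_o is edited to the nearest cograph; its canonical cotree is the gene
tree (series = speciation, parallel = duplication), and **Dollo
parsimony** maps each component onto the species tree: one gain above the
LCA of the observed species, losses on the minimal pruning branch set,
cotree duplications on the gain branch. Anticodon changes within
components are inferred by parsimony and classified *iso*/*allo* by
whether the decoded amino acid changes.

A forward simulator with full ground truth (genealogy, true orthology
edges, per-branch events, surviving remoldings) generates test data in
the same formats the pipeline consumes.

## Worked example

```sh
synterna simulate --seed 7 --out demo/sim
# simulated 167 genes, 21 anchors -> demo/sim

synterna run --genes demo/sim/genes.tsv --anchors demo/sim/anchors.tsv \
             --tree demo/sim/tree.nwk --out demo/out
# 24 components (4 singletons), 413 orthology edges, 10 duplications, 3 remoldings

synterna evaluate --truth demo/sim --result demo/out
# {"edge_precision": 0.9758, "edge_recall": 0.9853, "edge_f1": 0.9805}
```

The run reconstructed 24 co-ortholog components from 167 genes in six
species; 413 of the proposed orthology edges check out against the
simulated truth at F1 = 0.98. `demo/out/events.tsv` holds the per-branch
accounting (branch = child node of the species tree; `total_gain` =
components seeded + duplications, per the gain convention above):

```
branch  gains_seeding  duplications  total_gain  losses
Ggo     1              0             1           1
Mmu     1              0             1           0
Pab     2              0             2           0
n1      19             9             28          0
n2      1              1             2           0
```

Most components date to the root edge (`n1`: 19 seedings plus 9 ancestral
tandem duplications), with a handful of lineage-specific gains and one
loss on the gorilla branch — the low-turnover regime the defaults
simulate. `demo/out/remoldings.tsv` lists the inferred anticodon changes
with their branch and iso/allo class, e.g. an `AAG → ACG` (Lys → Thr,
allo) change on the human and chimp terminal branches.

Every stage's artifact is written alongside: `graph_{candidate,pruned,
estimated,edited}.tsv`, `clusters.tsv`, `alignments.tsv`, `cotrees.nwk`
(internal labels S/D), `introns.tsv`, and the resolved `config.yaml`.
The same steps are available as library calls
(`simulate → build_candidate_graph → prune_by_distance → align_clusters →
build_estimated_orthology → edit_components → summarize_events`, or
`reconstruct` for the whole chain).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end result from scratch: it simulates
replicate datasets with known ground truth, runs the full refinement
pipeline on each, verifies the stage-chain invariants, and reports
per-replicate orthology-edge F1 and remolding recovery on stderr before
writing the results JSON to `--out`.

## Documentation

`docs/methods.md` describes the model and its assumptions, every tunable
parameter with units and defaults, what the synthetic world does and does
not emulate, and known limitations.
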