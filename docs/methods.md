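# Methods

## Problem and pipeline

Integrated biomedical knowledge graphs (KGs) pool diseases, genes, drugs and
phenotypes from many source resources, with typed predicates between
concepts and dedicated *equivalence* predicates (`N_Name`, `I_CODE`,
`R_equivalentClass`, `R_exactMatch`) linking the same concept across
resources. Given such a KG and a seed cluster of diseases related to a
target condition, the pipeline ranks drug repurposing/repositioning
candidates in five stages:

1. **Extraction.** The profile network is the induced subgraph on the union
   of radius-3 ego balls around each seed disease. Traversal ignores edge
   direction by default (equivalence ties are symmetric; many domain
   predicates are reported in one arbitrary direction); `out`/`in` modes
   exist for sensitivity analysis. We take *induced* edges on the union
   rather than the union of per-ego edge sets: the two differ only at ball
   frontiers, and the induced form keeps the profile network a true
   subgraph of the KG.
2. **Contraction.** Connected components (size ≥ 2) of the
   equivalence-edge subgraph are each replaced by one merged node:
   attributes concatenated, intra-component edges removed, boundary edges
   reattached. Merging is transitive through connected components — A≡B and
   B≡C merge {A,B,C} — which is required for idempotence: after one pass no
   equivalence edge can survive, so contracting again is the identity.
   Merged labels are synonym-filtered: a label recorded in the synonym set
   of an earlier retained label is dropped (first-seen wins, so at least
   one label always survives). Reattached parallel edges with an identical
   predicate collapse to one; distinct predicates are all kept. Merged ids
   are `merged:<smallest member id>` for determinism. Note that rule 3
   introduces inference: a drug linked to one member becomes linked to the
   merged bundle. This is surfaced in the merge report rather than
   suppressed.
3. **Community detection.** Louvain modularity maximization on the
   undirected, unweighted view at resolution γ (default 1.0), with a seeded
   RNG for the local-move order so runs are reproducible (`randomize=False`
   pins the shuffle to a constant instead). Each community c is scored by
   its own modularity contribution

   score(c) = L_c/m − γ·(k_c/2m)²,

   with L_c the internal edge count, k_c the member degree sum, and m the
   total (undirected) edge count. At γ=1 these scores sum to Newman's Q —
   the property the tests verify against an independent modularity
   implementation. Communities with three nodes or fewer are excluded from
   ranking; the rest are ordered by score descending, ties by index.
4. **Centrality.** Five measures per community subgraph (not the whole
   network — closeness and betweenness are deliberately community-local):
   raw degree (undirected edge count); Wasserman–Faust closeness (component
   -scaled so disconnected subgraphs still land in [0,1]; a per-component
   unscaled variant is available by flag); Brandes betweenness normalized
   by (n−1)(n−2)/2 so it reads as a fraction of other-pair shortest paths;
   eigenvector centrality by power iteration for a fixed count of
   iterations (default 100) from the uniform vector, max-normalized to
   [0,1]; PageRank on the directed view with damping 0.85, uniform dangling
   redistribution, stopping when the L1 change falls below 1e-3 (scores sum
   to 1).
5. **Ranking.** Per measure the top five nodes are taken (ties by node id),
   their raw scores min–max scaled to [0,1], and each node's Total
   Normalized Centrality Score (TNCS) is the sum of its five normalized
   scores, hence TNCS ∈ [0,5]; a node that is argmax of every measure
   scores exactly 5. The default `top5_union` scope normalizes only the
   top-five scores per measure (nodes outside a top five contribute 0);
   the `community_all` scope normalizes over the whole community. Both are
   implemented because either reading of the procedure is defensible, and
   the report records which was used. When a measure's values are all equal,
   scaling maps them to 0 — a conservative floor that keeps TNCS a lower
   bound — and the event is logged.

## Numerical choices

- **Eigenvector iteration.** Plain power iteration x ← Ax oscillates on
  bipartite graphs: on a star, even iteration counts make all scores equal,
  so the hub would not rank first. We iterate x ← (A+I)x, which has the same
  principal eigenvector, converges on every connected graph (λ₁+1 strictly
  dominates |λᵢ+1| for symmetric A), and is the standard remedy. Per-step
  max-normalization prevents overflow. Iteration count does not change the
  node ordering on our fixtures (checked at 50 vs 100 vs 200).
- **PageRank** uses the simple directed collapse of the multigraph
  (parallel predicates count once), matching the simple-adjacency
  convention used by the degree-type measures. On an undirected subgraph it
  treats every tie as reciprocal.
- **Average degree is E/N** (edges per node), not the conventional 2E/N;
  **density is E/(N(N−1))**, the directed form. These are the definitions
  under which the published example network (1,466 nodes, 107,423 edges)
  yields average degree 73.276 and density 0.05.
- **Diameter / average path length** on disconnected graphs are measured on
  the largest connected component of the undirected view; the component's
  coverage is reported as `lcc_fraction`.
- **Degenerate inputs.** Empty graph: stats/partition error. Edgeless
  graph: Louvain returns singletons (the natural limit; modularity itself
  is undefined at m=0, and the per-community score raises). Eigenvector
  centrality on an edgeless graph is undefined and raises. Single-node
  closeness component scores 0.

## Synthetic data

No desk-scale public release of an integrated multi-resource rare-disease
KG exists, so the generator plants the structure the pipeline consumes:

- concepts of four categories (default 80 diseases / 60 genes / 40 drugs /
  20 phenotypes) assigned to near-equal communities, with planted-partition
  edges (p_in = 0.3 within, p_out = 0.01 between, orientation random) —
  chosen so that community recovery is hard enough to be meaningful but
  achievable (ARI ≈ 1 at 200 nodes);
- one planted hub per community, connected to every other member: the
  known-correct answer for the candidate-ranking stage;
- cross-resource duplication: with probability 0.15 a concept is re-emitted
  under another resource, takes one of the original's synonyms as its
  primary label, gains one spurious alt-label (so synonym filtering has
  real work), and is linked to the original by a uniformly chosen
  equivalence predicate;
- a seed cluster of diseases drawn preferentially from community 0. The
  worked analysis uses a larger configuration (700 concepts, 8 communities,
  92 seed diseases, p_in = 0.15, p_out = 0.005) to mirror a cluster of one
  target disease plus 91 related diseases at a size that runs in seconds.

What the generator does **not** emulate: the heavy-tailed degree
distribution of real KGs (planted-partition edges are homogeneous), million
-node scale, category-dependent edge densities, and noisy/contradictory
equivalence links (every planted equivalence is correct). Passing tests
therefore demonstrate algorithmic correctness and recoverability of planted
structure, not performance on a production KG, where equivalence errors and
hub-dominated degree distributions would stress the contraction and
normalization steps differently.

## Validation strategy

Every measure and law is cross-checked against an implementation
independent of the package's code path: pure-python BFS for distances and
ego balls; literal shortest-path enumeration and distance-matrix pair
counting for betweenness; dense eigendecomposition for eigenvector; a
direct linear solve for PageRank; union-find for equivalence components;
networkx's Newman modularity for the score decomposition. The centrality
sweep covers every connected graph on ≤ 7 nodes (the full small-graph
atlas, 995 graphs) plus seeded random connected 8-node and 30-node graphs.
Oracle comparisons run the fixed-point iterations to tight convergence
(500 eigenvector iterations, PageRank epsilon 1e-12) so they test the
algorithm rather than the truncation; separate tests pin the behaviour of
the default 100-iteration / 1e-3 settings.

Problem sizes in the test suite and analysis (200–834 nodes, ≤ ~6,300
edges, 20–100 replicate seeds) keep the full run in well under a minute
while leaving every statistical check comfortably powered.

## Known limitations

- The contraction is fully automatic; the manual veto step a curator would
  apply to bad merges is out of scope, so a wrong equivalence edge in real
  data would propagate into a wrong bundle.
- Communities are not auto-labelled; the report carries labels and
  categories so a human can do what ontology-driven labelling would.
- Louvain's output is seed-dependent on graphs with weak structure;
  `partition_stability` quantifies this (pairwise co-clustering agreement
  across seeds) but no consensus clustering is attempted.
- Literature validation of ranked candidates is a manual, out-of-scope
  step; the pipeline's output is a ranked hypothesis list.
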