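# Methods

## Problem setting

The input is the output of an over-representation analysis: a table of gene
sets (pathways, GO terms) with their member genes, typically long and highly
redundant. `gsclust` reduces it by computing a pairwise gene-set distance
matrix, clustering the sets, and summarizing the clusters. Gene identifiers
are opaque case-sensitive strings; no mapping between identifier spaces is
attempted, so gene-set input, PPI table and ontology must share one
identifier vocabulary (the user's responsibility).

## Distance metrics

All metrics return values in [0, 1]; matrices are symmetric with an exactly
zero diagonal, and values within 1e-12 of a boundary are snapped onto it
before the invariants are enforced.

**Set-based.** Jaccard, Sørensen–Dice and Meet-Min are the standard overlap
ratios (complemented). They obey d_MM ≤ d_Dice ≤ d_Jaccard, since
I/min ≥ 2I/(|A|+|B|) ≥ I/|A∪B|. Cohen's kappa treats the two sets as
membership indicators over a gene universe and chance-corrects their
agreement; the raw 1 − κ can reach 2 for negative κ, so it is clamped to
[0, 1] to keep a single distance scale for the clustering stage. The default
universe is the union of all genes in the loaded collection — self-contained
and annotation-free — but callers with a known background can supply one.
A degenerate universe (expected agreement 1) falls back to the exact-match
rule (0 if the sets are equal, else 1) with a warning.

**PPI-weighted Meet-Min (pMM).** The smaller set S (ties broken to the
first argument, and matrix construction always passes the pair in label
order, making the result call-order independent) is scored against the
larger set L:

    d = 1 − [ |A∩B| + α · Σ_{g ∈ S\L} max_{h ∈ L} w(g, h) ] / |S|,  clamped to [0, 1]

with α ≥ 0 (default 1). Lookups of absent genes or pairs return weight 0,
so pMM degrades exactly to Meet-Min on an empty network, is bounded above by
Meet-Min for every network, and is monotone: raising any single interaction
weight can only decrease distances. STRING-style combined scores are
rescaled by `score_scale` (default 1000) and clamped; duplicate edges keep
the maximum weight (strongest evidence), self-loops are dropped and counted.

**Wang semantic distance.** S-values are computed by breadth-first maximum
relaxation from the query term along child→parent edges, multiplying by the
edge factor (is_a 0.8, part_of 0.6; any other relationship is treated as
part_of). Because every factor is < 1, the maximum-product relaxation
converges on a DAG, and the unit tests check it against an explicit
path-enumeration oracle on random DAGs of ≤ 20 terms at 1e-9. Terms in
disconnected components share no ancestors and get distance 1 with a
warning. Only the term ids are consulted, so the semantic metric applies
when gene-set ids are ontology term ids.

## Clustering

The threshold graph has an edge where distance is strictly below tau
(default 0.5) with weight 1 − d; all labels are nodes, so isolated sets
yield singleton clusters. Louvain (seeded, modularity on the edge weights)
and MCL run on this graph; using the thresholded rather than the complete
weighted graph matches the network-view semantics of the threshold
parameter.

MCL adds self-loops of weight 1, column-normalizes, and alternates matrix
power (expansion 2), elementwise power (inflation 2) with renormalization,
and pruning of entries below 1e-5, stopping at numerical idempotence
(max |Δ| < 1e-8) or 100 iterations (non-convergence is flagged, and the
current interpretation returned). Clusters are read from attractor rows;
a node attracted by several attractors joins the lowest-index cluster so the
output remains a partition — MCL's rare overlaps are deliberately lost
because downstream ARI needs hard labels.

PAM is the classic BUILD + SWAP k-medoids on the raw distance matrix, fully
deterministic with ties broken to the lowest label index. When k is not
supplied it is chosen to maximize mean silhouette over k ∈ [2, min(n−1, 20)]
(singletons score 0); the cap keeps the search at desk scale and an explicit
k always wins.

Fuzzy clustering follows the DAVID scheme on similarity S = 1 − d: (1) each
label seeds its neighbourhood {i} ∪ {j : S_ij ≥ sim_threshold}; seeds
smaller than min_seed_size (3) or with a within-seed fraction of similar
pairs below membership_threshold are discarded; (2) seeds whose shared
member fraction |X∩Y|/min(|X|,|Y|) reaches linkage_threshold are merged in
deterministic lowest-index-first passes until a pass makes no merge;
(3) uncovered labels are emitted as singleton clusters flagged
"unclustered". All four thresholds default to 0.5. Note that a "bridge" set
similar to two otherwise-dissimilar groups can seed a mixed neighbourhood
whose internal agreement still clears 0.5, in which case merging unifies the
groups; raising membership_threshold rejects such mixed seeds and preserves
the two overlapping clusters (both behaviours are unit-tested).

## Robustness experiment

The experiment measures how stable Meet-Min vs pMM Louvain clusterings are
under random gene removal. For each removal size r, min(r, ⌊|genes|/2⌋)
genes are removed (uniformly, seeded) from every set with more than 10
genes; one reduced collection per r is shared across metrics so they face
identical perturbations. For each repetition, Louvain runs on the reduced
matrix and — with the matched seed — on the intact matrix, and the ARI
between the two partitions is recorded. Matched seeds isolate the effect of
gene removal from Louvain's own stochasticity, which is the cleaner contrast
when the question is metric robustness rather than algorithm variance.
Sub-seeds are CRC32 hashes of (master seed, context), folded below 2^31, so
any grid cell can be recomputed independently. Defaults are removal sizes
1–15 with 100 repetitions; the test suite and the acceptance script use
sizes {1, 5, 10} with 10 repetitions, which already separates the regimes
while completing in seconds.

## Synthetic fixtures

The planted-collection generator emulates a redundant enrichment result:
k disjoint per-theme gene pools plus a shared background; each set draws
round(core_fraction · set_size) genes from its theme pool and the rest from
background, without replacement, under a seed. The synthetic PPI connects
within-pool gene pairs densely and strongly (w_in 0.9, p_in 0.3) and all
other pairs sparsely and weakly (w_out 0.2, p_out 0.01), mimicking the
within-pathway enrichment of real interaction networks. The canonical
instance (5 themes × 6 sets of 25 genes, core fraction 0.8, pools of 60,
background 300, fixed seed) is frozen in code so every recovery and
robustness property references one reproducible object.

What the fixture does *not* emulate: realistic GO hierarchies, heavy-tailed
set-size distributions, p-value structure, or identifier noise. On the
canonical instance the theme pools (60 genes) are generous relative to the
sets, so within-theme overlap is moderate: Meet-Min distances within a theme
sit near 0.73, above the 0.5 threshold, and overlap-only threshold graphs on
this fixture are edgeless (every set a singleton) while the PPI-weighted
distances (≈ 0.08–0.24 within, ≈ 0.95 between) separate the themes sharply.
Recovery results on the fixture therefore demonstrate the PPI-weighted
pipeline; they do not show that overlap-only metrics recover these
particular planted themes, and on this fixture both metrics are fully robust
to removal (ARI ≡ 1, a degenerate but correct ordering). The tight-overlap
stress regime (pools of 25) in the evaluation tests is the informative case:
overlap clusters exist, break under removal (Meet-Min mean ARI 0.17 at
r = 10), and the interaction term preserves them (pMM ARI 1.0). Passing
tests on synthetic data say nothing about annotation quality or PPI coverage
in real organisms.

## Reports and summaries

Heatmap ordering is the leaf order of average-linkage hierarchical
clustering (average linkage as a robust default for bounded
dissimilarities). Word-cloud input is a per-cluster token count over member
descriptions (lowercase, punctuation stripped, stopwords and tokens shorter
than 3 characters dropped; counts sorted by frequency then alphabetically);
rendering an actual word-cloud image is out of scope — the frequency table
is the tested artifact. The bipartite graph namespaces gene-set and cluster
nodes to avoid id collisions and keeps flagged singletons so every input set
is accounted for. The HTML report is a single self-contained file (figures
embedded as base64 PNG with stripped metadata) and is byte-identical across
runs when the timestamp is disabled; external database links are constructed
by string templating from id prefixes (GO:, R-, map) only.

## Limitations

* The pMM interaction term uses the maximum edge weight into the other set;
  it does not integrate multiple weaker interactions per gene.
* Only is_a/part_of ontology relations contribute to the semantic metric;
  information-content measures (Resnik/Lin) are not implemented.
* `fetch_interactions` is a thin convenience wrapper; only its cache path is
  tested, and identifier compatibility with the gene-set input is not
  checked.
* Fuzzy clustering output depends on the deterministic merge order; other
  orderings can give different (equally valid) overlapping covers.
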