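# gsclust

Functional-enrichment analysis (over-representation tests against GO, KEGG,
Reactome, MSigDB, ...) routinely returns hundreds of overlapping gene sets,
which buries the underlying biology in redundancy. `gsclust` is a scriptable
toolkit for the downstream step: it quantifies the pairwise (dis)similarity
of the reported gene sets, aggregates them into functionally coherent
clusters, and renders shareable summaries — so a 400-row enrichment table
becomes a handful of interpretable themes. It is aimed at bioinformaticians
post-processing bulk or single-cell RNA-seq enrichment results from tools
such as topGO, clusterProfiler, ReactomePA, enrichR or fgsea.

## Distance metrics

For gene sets $A$, $B$ with intersection size $I = |A \cap B|$, `gsclust`
implements distances in $[0, 1]$:

* **Jaccard** $d = 1 - I/|A \cup B|$, **Sørensen–Dice**
  $d = 1 - 2I/(|A|+|B|)$, **Meet-Min** $d = 1 - I/\min(|A|,|B|)$, and
  **Cohen's kappa** $d = \mathrm{clamp}(1-\kappa, 0, 1)$ over a gene
  universe — all driven purely by overlap.
* **pMM**, a PPI-weighted Meet-Min: with $S$ the smaller set and $L$ the
  larger,

  $$d_{\mathrm{pMM}} = 1 - \frac{I + \alpha \sum_{g \in S \setminus L}
  \max_{h \in L} w(g, h)}{|S|},$$

  where $w$ is the interaction weight (e.g. a STRING combined score / 1000)
  and $\alpha \ge 0$ balances the network term. Non-shared genes that
  interact strongly with the other set still count as evidence of shared
  function, so $d_{\mathrm{pMM}} \le d_{\mathrm{MM}}$ always, with equality
  on an empty network.
* **Wang semantic distance** on an ontology DAG: each ancestor $u$ of a term
  $t$ carries $S_t(u) = \max_{\text{paths}} \prod w_e$ (edge factors 0.8 for
  `is_a`, 0.6 for `part_of`), and
  $d = 1 - \sum_{u \in \mathrm{anc}(A) \cap \mathrm{anc}(B)}
  (S_A(u) + S_B(u)) / (SV(A) + SV(B))$.

Clustering algorithms on the resulting matrix: **Louvain** and **Markov
(MCL)** community detection on the threshold graph (edge iff $d < \tau$,
weight $1-d$), **PAM** k-medoids (silhouette-chosen $k$ when unspecified),
and DAVID-style **fuzzy clustering** with overlapping membership. An
**ARI-based robustness experiment** contrasts Meet-Min and pMM clustering
stability under random gene removal.

## Worked example

```python
import gsclust as g

# canonical synthetic fixture: 5 planted themes x 6 sets of 25 genes,
# plus an interaction network enriched within the themes
collection, planted, ppi = g.canonical_fixture()

dm = g.distance_matrix(collection, g.MetricParams(metric="pmm"), ppi=ppi)
result = g.louvain_cluster(dm, g.ClusteringParams(tau=0.5, seed=1))
print(result.n_clusters)                      # 5
for c in result.clusters[:2]:
    print(sorted(c)[:3], "...")

res = g.gene_removal_robustness(collection, ppi,
                                removal_sizes=[1, 5, 10],
                                repetitions=10, seed=1)
print(res.summary())
```

prints

```
5
['S00_00', 'S00_01', 'S00_02'] ...
['S01_00', 'S01_01', 'S01_02'] ...
    metric  removal_size  mean  std
0  meetmin             1   1.0  0.0
1  meetmin             5   1.0  0.0
2  meetmin            10   1.0  0.0
3      pmm             1   1.0  0.0
4      pmm             5   1.0  0.0
5      pmm            10   1.0  0.0
```

The five Louvain clusters coincide exactly with the planted themes, and on
this well-separated fixture both metrics are fully stable under removal
(mean ARI 1.0 against matched-seed clusterings of the intact data). In a
tighter-overlap regime (per-theme gene pools barely larger than the sets,
see `tests/test_evaluation.py::stress_fixture`) Meet-Min stability collapses
to ARI ≈ 0.17 at removal size 10 while pMM stays at 1.0 — the interaction
network retains the grouping signal that overlap alone loses.

A full session (read → filter → distances → clustering → HTML report) runs
from a YAML config:

```sh
gsclust simulate --out fixture/
gsclust run --config session.yaml     # see gsclust.pipeline for the schema
```

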