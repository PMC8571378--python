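# tilseq

Analysis toolkit for studying how a single tumor neoepitope shapes the
anti-tumor immune response in vivo, combining three data modalities from the
same experiment:

1. **Tumor-infiltrating leukocyte (TIL) scRNA-seq** — quality control,
   TF-IDF informative-gene selection, Ward clustering, one-vs-all Welch
   differential expression and marker-panel annotation of 10x-style UMI count
   matrices, plus a library-level transcriptome hierarchy with bootstrap
   branch confidence.
2. **TCR repertoires** — GLIPH-style specificity networks over clonotypes
   (CDR3β + V gene): *global* edges between CDR3s at Hamming distance ≤ 1 and
   *local* edges between clonotypes sharing an enriched interior motif
   (≥ 10-fold over a naive reference at resampling probability < 0.001),
   followed by Louvain community detection and modularity-based diversity
   scoring.
3. **Tumor growth curves** — per-mouse area-under-curve and the 0–5 tumor
   rejection score (TRS) per immunization group.

A synthetic-data module generates all three modalities with planted ground
truth (cell types, QC violators, specificity groups, mouse outcomes), so the
entire pipeline is testable end to end without any external download.

## The statistics at the core

**TF-IDF gene scoring.** Treating cells as documents and genes as terms,
`score(g) = (1/N) Σ_c TF(g,c)·IDF(g)` with `TF(g,c) = count(g,c)/total(c)`
and `IDF(g) = log2(N/df(g))`, where `df(g)` is the number of cells detecting
gene *g*. Genes detected in every cell score exactly 0; the top ~1,500 genes
by average score are the clustering features.

**Graph modularity.** For a binary specificity network with adjacency `A`,
degrees `k`, `m` edges and community labels `c`,

```
Q = 1/(2m) · Σ_ij (A_ij − k_i k_j / (2m)) · δ(c_i, c_j)
```

Louvain partitions maximize Q; the repertoire diversity summary is the mean
Q over the connected components housing the most clonally expanded TCRs —
many well-separated specificity groups score high, a repertoire dominated by
one dense group scores near 0.

**Tumor rejection score.** For a group of *n* challenged mice,
`TRS = 5 · (n_complete + w·n_partial)/n` (default partial-control weight
`w = 0.5`), so 5.0 means every mouse rejected the tumor and 0 means none did.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from tilseq import simulate, sc, tcr, growth, io as tio

# four simulated TIL libraries with planted cell types and QC violators
adatas, truth = simulate.simulate_counts(simulate.CountSimConfig(seed=7))
pooled = tio.concat_libraries(adatas.values())
metrics = sc.compute_qc_metrics(pooled.X, pooled.var_names, pooled.obs_names)
kept = sc.qc_filter(metrics)
print(f"QC kept {len(kept)} of {pooled.n_obs} cells")

X = np.asarray(pooled[kept].X.todense())
selector = sc.TfidfGeneSelector(k=1500, gene_names=list(pooled.var_names)).fit(X)
labels = sc.ward_cluster(sc.log_transform(selector.transform(X)), 6)
types = truth.obs.loc[kept, "cell_type"]
print(f"Ward ARI vs planted types: {adjusted_rand_score(types, labels):.3f}")

# tumor growth scoring of a protected and an unprotected group
table, _ = simulate.simulate_growth(simulate.GrowthSimConfig(seed=7))
per_mouse, groups = growth.summarize_groups(table)
print(groups[["group", "n_mice", "n_complete", "mean_auc", "trs"]].round(1).to_string(index=False))
```

prints

```
QC kept 1952 of 2000 cells
Ward ARI vs planted types: 1.000
 group  n_mice  n_complete  mean_auc  trs
group1       5           5     102.8  5.0
group2       5           0     612.7  0.0
```

The 48 excluded cells are exactly the planted QC violators (12 per library:
high total UMIs, too few detected genes, > 10% mitochondrial or < 5%
ribosomal content); the clustering recovers the planted six cell types
perfectly; the fully protected group earns the maximal TRS of 5.0 while the
progressing control group scores 0.

The same chain is available from the shell:

```sh
tilseq simulate --seed 7 --out data/
tilseq report --in data/ --out results/ --seed 7
```

which writes QC metrics, cluster labels, per-cluster differential-expression
tables with annotations, the library dendrogram (Newick with bootstrap
supports), per-library TCR networks (GraphML + edge/motif/summary TSVs) and
growth scores.

## Layout

```
src/tilseq/
  io.py         # Cell Ranger triplet, 10x contig CSV, growth CSV, YAML config
  simulate.py   # synthetic counts / repertoires / growth curves with truth
  sc.py         # QC, TF-IDF, Ward, Welch DE, annotation (sklearn estimators)
  hierarchy.py  # library profiles, complete linkage, bootstrap supports
  tcr.py        # clonotypes, similarity edges, enrichment, Louvain, Q
  growth.py     # AUC, outcome classification, TRS
  cli.py        # `tilseq` command with per-stage subcommands
docs/methods.md # models, assumptions, parameter choices, limitations
```
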