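# Methods

This note documents the models and procedures implemented in `tilseq`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Cell quality control

Cells are summarized by total UMI count, number of detected genes,
mitochondrial fraction (genes prefixed `mt-`) and ribosomal fraction (genes
prefixed `Rps`/`Rpl`; both prefixes configurable, matching mouse
nomenclature). A cell is excluded when **any** strict comparison fires:

| rule | default | meaning |
| --- | --- | --- |
| total UMIs > `max_total_umis` | 30 000 | suspected doublet / outlier |
| detected genes < `min_genes` | 500 | low-complexity cell |
| detected genes > `max_genes` | 5 000 | suspected doublet |
| mito fraction > `max_mito` | 0.10 | stressed or dying cell |
| ribo fraction < `min_ribo` | 0.05 | degraded library |

All comparisons are strict, so a cell sitting exactly on a boundary is kept.
The low-ribosomal rule is unusual — most workflows filter *high* ribosomal
content — but it is implemented as stated because the ribosomal fraction of
intact leukocytes is substantial and a very low value indicates RNA
degradation; it is configurable for users who disagree. Fractions of an
all-zero cell are defined as 0 (such a cell is excluded by the gene-count
rule anyway). Filtering is idempotent and independent of cell order.

## Transformation and feature selection

All expression-space analyses operate on `log2(x + 1)` of raw UMI counts; no
depth normalization is applied beyond the within-cell term frequency used by
the gene scores (the upstream aggregation of libraries is assumed
depth-matched, as produced by the standard multi-library pipelines).

TF-IDF gene scores are computed on raw counts **after** QC: the term
frequency is the gene's fraction of its cell's UMIs, the inverse document
frequency is `log2(N/df)` with `df` the number of cells detecting the gene,
and the score is the average of TF·IDF over all N cells, zeros included.
This formulation makes everywhere-detected genes score exactly 0 and rewards
genes that are both restricted and abundant where expressed — the intended
notion of an "informative" gene. The default feature set is the top
`k = 1500` genes, ties broken by lexicographic gene symbol for determinism.

## Clustering and annotation

Clustering is Ward agglomeration on Euclidean distances over the
log-transformed selected genes (scipy linkage; deterministic for fixed
input), cut to a configured number of flat clusters. The shipped defaults
mirror the analysis this package reproduces: 2 major compartments, 6
lymphoid, 9 myeloid and 7 T-cell sub-clusters.

Cluster annotation runs a one-vs-all Welch (unequal-variance) t-test per
gene on log-transformed values; the fold change is the difference of group
means in log2 space, so it is consistent with the t-test inputs. A gene
passes at `p < 0.01` and `|log2FC| > 1` (the annotation set); a reporting
set at 1.5-fold and `p < 0.05` is also exposed. No multiple-testing
correction enters the pass flag — the raw p-value is deliberately paired
with an effect-size cutoff — but a Benjamini–Hochberg q-value column is
provided for users who want it. A cluster is named after the marker panel
with the most up-regulated passing genes (`unassigned` if none,
`ambiguous` on ties). Panels ship with the conventional mouse markers
(CD8 T: *Cd3e, Cd8a, Cd8b1*; NKC: *Ncr1, Nkg7, Fcer1g*; macrophage: *Mrc1,
Adgre1, Itgam*; DC: *Zbtb46, Flt3, H2-Oa*; monocyte: *Itgam, Ly6c, Ms4a4c,
Il1b*; neutrophil: *S100a8, S100a9, Itgam*). The CD4 T panel (*Cd3e, Cd4,
Cd28*) is a package choice: CD4 cells are conventionally defined by CD3
positivity with CD8 negativity, which a positive-marker panel cannot
express directly. Fine sub-annotations (naive/early-activated CD4 via high
*Sell/Il7r/Tcf7/Ccr7* and low *Il2ra*) are exposed as configurable panels
rather than hard-coded, because the quantitative "low" cutoff is not
well-defined.

A cluster dominated by proliferation is detected by comparing its mean
expression over a bundled cell-cycle gene list (a curated set of ~50 mouse
proliferation genes) to the grand mean across clusters; clusters exceeding
`ratio = 2` are flagged for exclusion from pooled downstream analyses.

## Library hierarchy

Each library is represented by its mean log2 expression over the selected
top genes, normalized per gene by the maximum across libraries (the same
row-max rule used for the cluster heat maps; rows with maximum 0 stay 0).
Libraries are compared by Euclidean distance and agglomerated by complete
linkage. The linkage is implemented directly (the pair with the smallest
maximum inter-point distance merges at that height) with an explicit
tie-break toward the lexicographically smallest combined label set, making
the topology independent of input order; scipy's implementation serves as an
independent oracle in the tests.

Branch confidence is a **gene-level bootstrap**: the selected gene set is
resampled with replacement B times (default 200), the profile →
normalization → distance → tree chain is rebuilt per replicate, and a
branch's support is the fraction of replicate trees containing the same
leaf bipartition. A gene bootstrap is the standard way to attach confidence
to an expression-derived dendrogram when no replicate libraries exist; it
asks whether the topology is driven by many genes or by a few.

## TCR specificity networks

Clonotypes are keyed by (CDR3β amino-acid sequence, V gene) — the β-chain
GLIPH convention — with size equal to the number of distinct cell barcodes.
Contig tables are pre-filtered to productive, high-confidence TRB rows; when
several TRB contigs survive for one barcode the highest-UMI contig wins
(ties to the lexicographically smallest CDR3).

Two edge types connect clonotypes:

* **global** — equal-length CDR3s at Hamming distance ≤ 1 (distance 0
  occurs between identical CDR3s on different V genes). Implemented by
  wildcard-position hashing; an all-pairs scan is the test oracle.
* **local** — sharing of at least one *enriched* motif: a contiguous
  2–4-mer from the CDR3 interior (trimming three germline-dominated residues
  from each end) whose sample frequency is ≥ 10× its frequency in a naive
  reference repertoire with resampling probability < 0.001. The probability
  is the fraction of subsamples of the reference (sample-sized, drawn
  without replacement; 10 000 by default, and a warning is raised below
  1 000 because the 0.001 threshold cannot be resolved) in which the motif
  appears at least as often as observed; this converges to the
  hypergeometric tail, which the tests verify. Unseen motifs get a floored
  reference frequency of `1/(N_ref + 1)` to keep folds finite. Only motifs
  carried by ≥ 2 sample clonotypes are tested, since a singleton motif
  cannot form an edge. The reference repertoire is an explicit input; no
  external reference is bundled, and the simulator produces a matched one.

The network fraction is the share of distinct clonotypes with at least one
edge. Communities come from igraph's Louvain (multilevel) algorithm with a
pinned seed (igraph draws its sweep order from Python's `random`, which is
seeded locally and restored); modularity is evaluated by this package's own
exact implementation, restructured as `Q = S_A/(2m) − Σ_c (Σ_{i∈c} k_i)²/(2m)²`
so that with integer degrees the one-community partition returns exactly
0.0 rather than a rounding residue.

The per-library diversity summary — *expanded-community modularity* — takes
the 10 most expanded clonotypes (ties toward higher degree, then
lexicographic CDR3), finds every connected component containing at least one
of them and at least 3 nodes, Louvain-partitions each component and averages
the resulting Q values. Whole-graph per-community contributions cannot reach
the 0.5–0.8 magnitudes this summary is meant to live on; scoring components
makes a repertoire of many well-separated specificity groups score high and
a repertoire collapsed onto one dense group score near 0. When no component
qualifies the summary is NaN and flagged via `n_components_used = 0`.

## Tumor growth scoring

Per-mouse AUC is the trapezoidal integral of tumor area over observed days,
first to last, with no extrapolation; a mouse euthanized early simply
truncates at its last observation. Outcomes derive from the final observed
area: ≤ 0 (configurable `complete_threshold`) is complete rejection, ≤ 10
area units (`partial_threshold`, same units as the input areas) is partial
control, otherwise progression. The group score is
`TRS = 5·(n_complete + w·n_partial)/n` rounded to one decimal, with
`w = 0.5` by default: fractional published TRS values imply partial credit
but no allocation rule is stated, so the weight is a parameter rather than a
guess baked in.

## Synthetic data: what it emulates and what it does not

The generators define the standard study conditions used by the tests.

**Counts** (`CountSimConfig`): 4 libraries × 500 cells, 2 000 genes, 6 cell
types, 17 markers per type (102 markers total). Counts are gene-wise
negative binomial (dispersion 2) with lognormal mean heterogeneity; marker
genes are multiplied by `2^marker_log2_effect` in their own type. The
default effect is 3 (8-fold): canonical cell-type markers (*Cd8a*, *S100a8*,
…) are near on/off between types, and at 2 000 cells this regime lets Ward
clustering recover the planted types essentially perfectly, while the
feature-selection tests additionally exercise the harder 2-fold regime.
Thirteen `mt-` genes and 100 `Rps`/`Rpl` genes with elevated means give
clean cells ~4 % mitochondrial and ~20 % ribosomal content, leaving wide
margins to the QC thresholds; clean cells are rejection-sampled to satisfy
all QC rules, and 12 violators per library (3 per rule) are constructed from
clean templates so that each breaks **exactly** one threshold. Per-library
cell-type proportions are configurable, which is how composition contrasts
and shared-program library pairs are planted. Not emulated: gene–gene
co-expression beyond the planted type structure, batch effects, ambient RNA
and doublet transcriptomes — so passing tests demonstrate correctness of the
pipeline's logic, not robustness to those artifacts.

**Repertoires** (`RepertoireSimConfig`): 60 clonotypes per library; CDR3s of
length 12–18 with fixed C…F termini and uniform amino-acid composition;
clone sizes geometric(p = 0.4) — the simplest one-parameter expansion law,
chosen because no empirical clone-size distribution was available to match.
Eight specificity groups of 3–5 members each share a planted interior
3-mer; with probability `bridge_probability` (default 0.5) one member of a
group also carries the previous group's motif, chaining groups into larger
components with genuine community structure (the diversity-ordering test
uses probability 1 for the diverse scenario and a single 15-member group
for the dominated one). The naive reference (1 000 CDR3s) is resampled
until every planted motif sits at ≤ 1/10 of its in-sample frequency, so
10-fold enrichment holds by construction. V(D)J recombination biases and
paired-chain structure are not modeled.

**Growth** (`GrowthSimConfig`): exponential growth at 0.15/day from
4 mm², rejection onset at day 9 with decay 0.5/day, measurements every
3 days to day 21, multiplicative lognormal noise (sd 0.2), and a detection
floor of 0.25 mm² below which areas record as 0 — which is what guarantees
complete rejecters end at exactly 0. Partial controllers plateau at
4 mm², safely inside the partial-control window even at 3σ noise.

## Numerical choices

* Welch test p-values are clipped to `(tiny, 1]`; genes constant in both
  groups get `t = 0, p = 1` (no evidence) rather than NaN.
* Modularity uses the exact integer-arithmetic restructuring described
  above; the brute-force double loop over ordered pairs is the test oracle
  at 1e-12.
* Ward and complete-linkage are deterministic; tie-breaks are lexicographic
  where scipy does not define them.
* TRS is rounded to one decimal, matching its reporting precision.
* Seeds: every stochastic routine (simulators, bootstrap, enrichment
  resampling, Louvain sweep order) takes an explicit seed and is
  reproducible byte-for-byte through the writers.

## Problem sizes used by the test suite

The standard fixtures are 2 000 cells × 2 000 genes for expression recovery,
3 × 300 cells for hierarchy bootstrap (B = 200), 60-clonotype repertoires
with 2 000 enrichment resamples for the diversity ordering (20 seed pairs),
and 10 000 resamples against a 100-sequence reference for enrichment
calibration. These sizes keep the full suite fast while leaving all
recovery margins wide (ARI ≈ 1.0 vs the 0.9 bound; bootstrap support 1.0 vs
the 0.9 bound; 20/20 diversity-ordering wins vs the 18/20 bound).

## Known limitations

* The 2D t-SNE/UMAP embeddings often drawn for such data are intentionally
  out of scope (cosmetic); so are batch correction, ambient-RNA removal and
  read-level processing.
* The enrichment reference is user-supplied; results depend on its
  realism, and the resampling probability saturates at 0 below the
  resolution `1/n_resamples`.
* The expanded-community modularity interpretation (mean over components
  housing expanded clones) is one of several defensible readings of a
  community-level diversity score; it is documented, seeded and easily
  swapped.
* Group-comparison inference on AUCs (ANOVA/Tukey) is deliberately left to
  general statistics packages; the per-mouse AUC table is exported for that
  purpose.
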