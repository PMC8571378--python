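"""Single-cell expression analysis: QC, TF-IDF feature selection, Ward
clustering, one-vs-all Welch differential expression and marker annotation.

The workhorse steps are exposed both as plain functions and as scikit-learn
compatible estimators (:class:`TfidfGeneSelector`, :class:`Log2Transformer`,
:class:`WardCluster`) so the expression chain composes with
``sklearn.pipeline.Pipeline``.  Matrices are oriented cells x genes
(observations x features) throughout, matching both AnnData and scikit-learn
conventions.

TF-IDF treats a cell as a document and a gene as a term: the term frequency is
the gene's fraction of the cell's UMIs and the inverse document frequency is
``log2(N / df)`` where ``df`` is the number of cells expressing the gene.  A
gene detected in every cell is maximally uninformative and scores exactly 0;
genes expressed strongly in a restricted subset of cells score highest, which
is what makes the average score a useful cluster-free feature-selection
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data


# ---------------------------------------------------------------------------
# QC metrics and filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Cell-exclusion cutoffs; all comparisons are strict.

    A cell is excluded when its total UMI count exceeds ``max_total_umis``, it
    expresses fewer than ``min_genes`` or more than ``max_genes`` genes, its
    mitochondrial fraction exceeds ``max_mito``, or its ribosomal fraction
    falls below ``min_ribo``.  Note the ribosomal rule is a *lower* bound:
    cells with under 5% ribosomal content are treated as low quality.
    """

    max_total_umis: int = 30000
    min_genes: int = 500
    max_genes: int = 5000
    max_mito: float = 0.10
    min_ribo: float = 0.05

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not (0.0 < self.max_mito < 1.0 and 0.0 < self.min_ribo < 1.0):
            raise ValueError("fraction thresholds must lie in (0, 1)")


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def compute_qc_metrics(
    X,
    gene_names: Sequence[str],
    cell_ids: Sequence[str] | None = None,
    mito_prefix: str = "mt-",
    ribo_prefixes: Sequence[str] = ("Rps", "Rpl"),
) -> pd.DataFrame:
    """Per-cell totals, detected-gene counts and mito/ribo fractions.

    ``X`` is a cells x genes count matrix.  Fractions of an all-zero cell are
    defined as 0.
    """
    X = _dense(X)
    gene_names = np.asarray(gene_names, dtype=object)
    mito = np.array([str(g).startswith(mito_prefix) for g in gene_names])
    ribo = np.array([str(g).startswith(tuple(ribo_prefixes)) for g in gene_names])
    total = X.sum(axis=1)
    safe_total = np.where(total > 0, total, 1)
    metrics = pd.DataFrame(
        {
            "total_umis": total.astype(np.int64),
            "n_genes": (X > 0).sum(axis=1).astype(np.int64),
            "mito_frac": X[:, mito].sum(axis=1) / safe_total,
            "ribo_frac": X[:, ribo].sum(axis=1) / safe_total,
        },
        index=None if cell_ids is None else pd.Index(cell_ids),
    )
    return metrics


def qc_violations(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Boolean table of which strict QC rule each cell violates."""
    t = thresholds
    return pd.DataFrame(
        {
            "high_umi": metrics["total_umis"] > t.max_total_umis,
            "low_gene": metrics["n_genes"] < t.min_genes,
            "high_gene": metrics["n_genes"] > t.max_genes,
            "high_mito": metrics["mito_frac"] > t.max_mito,
            "low_ribo": metrics["ribo_frac"] < t.min_ribo,
        },
        index=metrics.index,
    )


def qc_filter(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.Index:
    """Indices of cells passing every QC rule, input order preserved."""
    keep = ~qc_violations(metrics, thresholds).any(axis=1)
    return metrics.index[keep]


# ---------------------------------------------------------------------------
# Transformation and TF-IDF feature selection
# ---------------------------------------------------------------------------

def log_transform(X) -> np.ndarray:
    """Elementwise ``log2(x + 1)`` of a non-negative count matrix."""
    X = _dense(X).astype(float)
    if np.any(X < 0):
        raise ValueError("log_transform requires non-negative input")
    return np.log2(X + 1.0)


def tfidf_gene_scores(X, gene_names: Sequence[str] | None = None) -> pd.Series:
    """Average TF-IDF informativeness score per gene.

    ``score(g) = mean_c TF(g, c) * IDF(g)`` over all N cells (zero cells
    included), with ``TF(g, c) = count(g, c) / total(c)`` and
    ``IDF(g) = log2(N / df(g))``; genes never detected score 0.
    """
    X = _dense(X).astype(float)
    if X.size == 0:
        raise ValueError("empty matrix")
    n_cells = X.shape[0]
    total = X.sum(axis=1, keepdims=True)
    tf = np.divide(X, total, out=np.zeros_like(X), where=total > 0)
    df = (X > 0).sum(axis=0)
    idf = np.where(df > 0, np.log2(n_cells / np.maximum(df, 1)), 0.0)
    scores = (tf * idf).mean(axis=0)
    index = pd.Index(gene_names) if gene_names is not None else pd.RangeIndex(X.shape[1])
    return pd.Series(scores, index=index, name="tfidf")


def select_informative_genes(scores: pd.Series, k: int = 1500) -> list:
    """The ``k`` top-scoring genes, ties broken by lexicographic gene id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored genes")
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    return order[:k]


class TfidfGeneSelector(SelectorMixin, BaseEstimator):
    """Select the top-k genes by average TF-IDF score.

    Fit on a raw (QC-filtered) count matrix; ``transform`` keeps the selected
    gene columns.  ``gene_names`` is only used for tie-breaking and for the
    ``selected_genes_`` attribute; column position breaks ties otherwise.
    """

    def __init__(self, k: int = 1500, gene_names: Sequence[str] | None = None):
        self.k = k
        self.gene_names = gene_names

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=1, dtype=float)
        names = self.gene_names if self.gene_names is not None else np.arange(X.shape[1])
        scores = tfidf_gene_scores(X, names)
        selected = select_informative_genes(scores, self.k)
        self.scores_ = scores
        self.selected_genes_ = list(selected)
        pos = {g: i for i, g in enumerate(scores.index)}
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[[pos[g] for g in selected]] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Stateless ``log2(x + 1)`` step for use inside pipelines."""

    def fit(self, X, y=None):
        validate_data(self, X, dtype=float)
        return self

    def transform(self, X):
        X = validate_data(self, X, reset=False, dtype=float)
        return log_transform(X)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

class WardCluster(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering on Euclidean distances.

    Deterministic for fixed input: merges minimize the increase in total
    within-cluster variance.  ``labels_`` holds the flat clustering obtained by
    cutting the tree at ``n_clusters``; ``linkage_`` keeps the full merge tree
    in scipy linkage format.
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        if not 1 <= self.n_clusters <= X.shape[0]:
            raise ValueError(f"n_clusters must lie in [1, {X.shape[0]}]")
        if X.shape[0] == 1:
            self.linkage_ = np.empty((0, 4))
            self.labels_ = np.zeros(1, dtype=int)
            return self
        self.linkage_ = linkage(X, method="ward")
        raw = fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        # relabel communities by first appearance for stable output
        _, first = np.unique(raw, return_index=True)
        remap = {raw[i]: rank for rank, i in enumerate(sorted(first))}
        self.labels_ = np.array([remap[r] for r in raw], dtype=int)
        return self


def ward_cluster(X_log, n_clusters: int) -> np.ndarray:
    """Flat Ward clustering of a log-transformed feature matrix."""
    return WardCluster(n_clusters=n_clusters).fit(X_log).labels_


# ---------------------------------------------------------------------------
# Differential expression and annotation
# ---------------------------------------------------------------------------

def differential_expression(
    X_log,
    labels: Sequence,
    target,
    gene_names: Sequence[str] | None = None,
    p_threshold: float = 0.01,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """One-vs-all Welch t-test per gene for ``target`` cluster.

    Operates on log2(x+1) values; the fold change is the difference of group
    means in that transformed space.  A gene passes when ``p < p_threshold``
    and ``|log2FC| > lfc_threshold``.  A Benjamini-Hochberg ``q_value`` column
    is provided for reporting but plays no role in the pass flag.
    """
    X_log = _dense(X_log).astype(float)
    labels = np.asarray(labels)
    in_mask = labels == target
    a, b = X_log[in_mask], X_log[~in_mask]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("target cluster and complement each need >= 2 cells")
    lfc = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = scipy.stats.ttest_ind(a, b, axis=0, equal_var=False)
    # genes constant in both groups carry no evidence
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    q = _benjamini_hochberg(p)
    index = pd.Index(gene_names) if gene_names is not None else pd.RangeIndex(X_log.shape[1])
    out = pd.DataFrame(
        {"log2_fold_change": lfc, "t": t_stat, "p_value": p, "q_value": q},
        index=index,
    )
    out["passed"] = (out["p_value"] < p_threshold) & (out["log2_fold_change"].abs() > lfc_threshold)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


#: Up-regulated marker genes used to name clusters.  Lymphoid panels cover
#: CD8/CD4 T cells and NK cells; myeloid panels cover macrophages, dendritic
#: cells, monocytes and neutrophils (mouse gene symbols).
MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "CD8 T": ("Cd3e", "Cd8a", "Cd8b1"),
    "CD4 T": ("Cd3e", "Cd4", "Cd28"),
    "NKC": ("Ncr1", "Nkg7", "Fcer1g"),
    "macrophage": ("Mrc1", "Adgre1", "Itgam"),
    "DC": ("Zbtb46", "Flt3", "H2-Oa"),
    "monocyte": ("Itgam", "Ly6c", "Ms4a4c", "Il1b"),
    "neutrophil": ("S100a8", "S100a9", "Itgam"),
}

#: Markers of naive / early-activated CD4 T cells (high Sell/Il7r/Tcf7/Ccr7,
#: low Il2ra); exposed for configurable fine-grained annotation.
NAIVE_CD4_MARKERS: tuple[str, ...] = ("Sell", "Il7r", "Tcf7", "Ccr7")


def annotate_cluster(
    de_table: pd.DataFrame,
    panels: Mapping[str, Sequence[str]] = MARKER_PANELS,
) -> str:
    """Name a cluster by the panel with the most up-regulated passing markers.

    Returns ``"unassigned"`` when no panel has a passing marker and
    ``"ambiguous"`` on a tie for the best panel.
    """
    up = set(de_table.index[(de_table["passed"]) & (de_table["log2_fold_change"] > 0)])
    counts = {label: len(up.intersection(genes)) for label, genes in panels.items()}
    best = max(counts.values(), default=0)
    if best == 0:
        return "unassigned"
    winners = [label for label, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else "ambiguous"


def load_cell_cycle_genes() -> list[str]:
    """Bundled cell-cycle gene list (mouse symbols, newline-delimited fixture)."""
    text = resources.files("tilseq.data").joinpath("cell_cycle_genes.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def flag_cell_cycle(
    X_log,
    labels: Sequence,
    gene_names: Sequence[str],
    cc_genes: Sequence[str],
    ratio: float = 2.0,
) -> dict:
    """Flag clusters dominated by cell-cycle expression.

    A cluster is flagged when its mean expression over the cell-cycle gene
    list exceeds ``ratio`` times the grand mean of that quantity across
    clusters.  Flagged clusters are meant to be excluded from pooled
    downstream analyses.
    """
    cc_genes = list(cc_genes)
    if not cc_genes:
        raise ValueError("empty cell-cycle gene list")
    X_log = _dense(X_log)
    gene_names = list(gene_names)
    cols = [gene_names.index(g) for g in cc_genes if g in gene_names]
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels))
    if not cols:
        return {c: False for c in uniq}
    sub = X_log[:, cols]
    cluster_means = {c: sub[labels == c].mean() for c in uniq}
    grand = float(np.mean(list(cluster_means.values())))
    return {c: bool(cluster_means[c] > ratio * grand) for c in uniq}


# ---------------------------------------------------------------------------
# Composition and heat-map summaries
# ---------------------------------------------------------------------------

def composition_by_library(
    annotations: Sequence,
    library_of_cell: Sequence,
    grouping: Mapping | None = None,
) -> pd.DataFrame:
    """Percentage of each cell group per library; rows sum to 100.

    ``grouping`` optionally collapses fine annotations into super-groups
    (e.g. lymphoid vs myeloid) before tabulating.
    """
    ann = pd.Series(list(annotations), name="group")
    if grouping is not None:
        ann = ann.map(lambda a: grouping.get(a, a))
    tab = pd.crosstab(pd.Series(list(library_of_cell), name="library"), ann)
    return tab.div(tab.sum(axis=1), axis=0) * 100.0


def cluster_mean_summary(
    X_log,
    labels: Sequence,
    genes: Sequence[str],
    gene_names: Sequence[str],
    mode: str = "row_max",
) -> pd.DataFrame:
    """Genes x clusters matrix of normalized mean expression for heat maps.

    ``row_max`` divides each gene's cluster means by the row maximum (rows
    with maximum 0 stay 0); ``zscore`` standardizes each gene's means across
    clusters to mean 0 and population sd 1 (constant rows become all 0).
    """
    if mode not in ("row_max", "zscore"):
        raise ValueError(f"unknown mode {mode!r}")
    X_log = _dense(X_log)
    gene_names = list(gene_names)
    missing = [g for g in genes if g not in gene_names]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    labels = np.asarray(labels)
    uniq = sorted(pd.unique(labels))
    cols = [gene_names.index(g) for g in genes]
    means = np.column_stack([X_log[labels == c][:, cols].mean(axis=0) for c in uniq])
    out = pd.DataFrame(means, index=pd.Index(genes), columns=uniq)
    if mode == "row_max":
        row_max = out.max(axis=1)
        return out.div(row_max.where(row_max > 0, 1.0), axis=0)
    mu = out.mean(axis=1)
    sd = out.std(axis=1, ddof=0)
    return out.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0).where(sd > 0, 0.0)
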