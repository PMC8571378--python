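"""Library-level transcriptome hierarchy.

Each library is summarized by the mean log2(x+1) expression of the top
TF-IDF-selected genes, normalized per gene by the maximum across libraries.
Libraries are then compared by Euclidean distance and clustered with complete
linkage, and the confidence of each branch (bipartition of libraries) is
estimated by a gene-level bootstrap: the selected gene set is resampled with
replacement, the profile/distance/tree chain is rebuilt per replicate, and a
branch's support is the fraction of replicate trees that contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance


# ---------------------------------------------------------------------------
# Profiles and distances
# ---------------------------------------------------------------------------

def library_mean_expression(
    X_log,
    library_of_cell: Sequence,
    gene_names: Sequence[str],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Raw genes x libraries matrix of mean log expression (no normalization)."""
    X_log = np.asarray(X_log, dtype=float)
    libraries = pd.Series(list(library_of_cell))
    if libraries.empty:
        raise ValueError("profiles need at least one cell; a library has no cells")
    gene_names = list(gene_names)
    cols = [gene_names.index(g) for g in genes]
    uniq = list(dict.fromkeys(libraries))
    means = {}
    for lib in uniq:
        mask = (libraries == lib).to_numpy()
        if not mask.any():
            raise ValueError(f"library {lib!r} has no cells")
        means[lib] = X_log[mask][:, cols].mean(axis=0)
    return pd.DataFrame(means, index=pd.Index(genes))


def normalize_row_max(profile: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene row by its maximum across libraries (0 rows stay 0)."""
    row_max = profile.max(axis=1)
    return profile.div(row_max.where(row_max > 0, 1.0), axis=0)


def library_profiles(
    X_log,
    library_of_cell: Sequence,
    gene_names: Sequence[str],
    top_genes: Sequence[str],
) -> pd.DataFrame:
    """Normalized average expression vector per library over ``top_genes``."""
    return normalize_row_max(library_mean_expression(X_log, library_of_cell, gene_names, top_genes))


def pairwise_distances(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix between library profile columns."""
    labels = list(profiles.columns)
    d = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(profiles.to_numpy().T, metric="euclidean")
    )
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Complete-linkage dendrogram
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge history over a fixed leaf set.

    ``merges`` lists ``(left_members, right_members, height)`` tuples in merge
    order; members are sorted tuples of leaf labels.  Branch supports, when
    attached, map a frozenset of leaf labels (one side of the bipartition) to
    a fraction in [0, 1].
    """

    leaves: tuple
    merges: list
    supports: dict = field(default_factory=dict)

    def bipartitions(self) -> set:
        """Leaf sets of all internal nodes except the root."""
        out = set()
        for left, right, _ in self.merges:
            members = frozenset(left) | frozenset(right)
            if len(members) < len(self.leaves):
                out.add(members)
        return out

    def cophenetic(self, a, b) -> float:
        """Merge height at which leaves ``a`` and ``b`` first join."""
        for left, right, height in self.merges:
            if (a in left or a in right) and (b in left or b in right):
                return height
        raise KeyError((a, b))

    def to_newick(self, decimals: int = 4) -> str:
        """Newick string; bootstrap supports become internal node labels."""
        node: dict = {(leaf,): (str(leaf), 0.0) for leaf in self.leaves}
        rep = ""
        for left, right, height in self.merges:
            (ltxt, lh), (rtxt, rh) = node[left], node[right]
            lbranch = (height - lh) / 2.0
            rbranch = (height - rh) / 2.0
            members = tuple(sorted(left + right))
            support = self.supports.get(frozenset(members))
            label = "" if support is None else f"{support:.{2}f}"
            rep = f"({ltxt}:{lbranch:.{decimals}f},{rtxt}:{rbranch:.{decimals}f}){label}"
            node[members] = (rep, height)
        return rep + ";"


def complete_linkage_tree(distances: pd.DataFrame) -> Dendrogram:
    """Agglomerate by smallest maximum inter-point distance.

    At every step the pair of clusters with the smallest complete-linkage
    distance is merged at that height; exact ties are broken toward the pair
    whose combined, sorted member labels are lexicographically smallest, so
    the topology is independent of input order.
    """
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    labels = list(distances.columns)
    if len(labels) < 2:
        raise ValueError("need at least two leaves")
    pos = {lab: i for i, lab in enumerate(labels)}
    clusters: list[tuple] = [(lab,) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                height = max(d[pos[x], pos[y]] for x in a for y in b)
                key = (height, tuple(sorted(map(str, a + b))))
                if best is None or key < best[0]:
                    best = (key, i, j, height)
        (_, i, j, height) = best
        left, right = clusters[i], clusters[j]
        merges.append((left, right, height))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(tuple(sorted(left + right)))
    return Dendrogram(leaves=tuple(labels), merges=merges)


# ---------------------------------------------------------------------------
# Bootstrap branch support
# ---------------------------------------------------------------------------

def bootstrap_branch_support(
    X_log,
    library_of_cell: Sequence,
    gene_names: Sequence[str],
    top_genes: Sequence[str],
    n_replicates: int = 200,
    seed: int = 0,
) -> Dendrogram:
    """Full-data dendrogram annotated with gene-bootstrap branch supports.

    The per-library gene means are computed once; each replicate resamples the
    selected gene rows with replacement, re-normalizes, recomputes distances
    and the complete-linkage tree, and records its bipartitions.  The support
    of a branch of the full-data tree is the fraction of replicates whose tree
    contains the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    raw = library_mean_expression(X_log, library_of_cell, gene_names, top_genes)
    base = complete_linkage_tree(pairwise_distances(normalize_row_max(raw)))
    counts: dict = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    n_genes = raw.shape[0]
    values = raw.to_numpy()
    for _ in range(n_replicates):
        rows = rng.integers(0, n_genes, size=n_genes)
        rep = pd.DataFrame(values[rows], columns=raw.columns)
        tree = complete_linkage_tree(pairwise_distances(normalize_row_max(rep)))
        for bp in tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    base.supports = {bp: c / n_replicates for bp, c in counts.items()}
    return base
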