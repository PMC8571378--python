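"""GLIPH-style TCR specificity networks and community diversity scoring.

Clonotypes (CDR3beta amino-acid sequence + V gene) become network nodes.  Two
kinds of undirected edges are drawn: *global* edges between equal-length CDR3s
at Hamming distance <= 1, and *local* edges between clonotypes sharing an
enriched CDR3 motif.  Motifs are contiguous 2-4-mers taken from the interior
of the CDR3 (trimming three germline-dominated residues from each end) and a
motif is enriched when its sample frequency is at least 10-fold its frequency
in a naive reference repertoire with a resampling probability below 0.001.

Communities are found with Louvain modularity optimization (igraph) and graph
modularity is evaluated exactly as

    Q = 1/(2m) * sum_ij (A_ij - k_i k_j / (2m)) * delta(c_i, c_j)

over ordered node pairs, where ``m`` is the edge count, ``A`` the binary
adjacency, ``k_i`` the degree, and ``c_i`` the community of node ``i``.  The
diversity of a repertoire is summarized by the mean Louvain modularity of the
connected components housing the most expanded clonotypes: many well-separated
specificity groups score high, a repertoire dominated by one dense group
scores low.
"""

from __future__ import annotations

import random
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Clonotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clonotype:
    """A distinct TCR keyed by (CDR3beta, V gene); size = number of cells."""

    cdr3: str
    v_gene: str
    cell_count: int
    library: str = ""

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1")


def aggregate_clonotypes(contigs: pd.DataFrame) -> list[Clonotype]:
    """Collapse filtered contig rows to distinct (CDR3, V) clonotypes.

    ``cell_count`` is the number of distinct barcodes carrying the key.  The
    result is sorted by (CDR3, V gene) for deterministic node order.
    """
    if len(contigs) == 0:
        raise ValueError("empty contig table")
    grouped = (
        contigs.groupby(["cdr3", "v_gene"], sort=True)["barcode"].nunique().reset_index()
    )
    library = str(contigs["library"].iloc[0]) if "library" in contigs.columns else ""
    return [
        Clonotype(cdr3=row.cdr3, v_gene=row.v_gene, cell_count=int(row.barcode), library=library)
        for row in grouped.itertuples()
    ]


# ---------------------------------------------------------------------------
# Global similarity (Hamming <= 1 on equal-length CDR3s)
# ---------------------------------------------------------------------------

def global_similarity_edges(clonotypes: Sequence[Clonotype]) -> set[tuple[int, int]]:
    """Index pairs of clonotypes with equal-length CDR3s at Hamming distance <= 1.

    Distance 0 pairs arise for identical CDR3s carried by different V genes.
    Implemented by hashing each CDR3 once per wildcarded position, so near
    neighbours land in shared buckets without an all-pairs scan.
    """
    buckets: dict[tuple[int, int, str], list[int]] = defaultdict(list)
    for idx, ct in enumerate(clonotypes):
        s = ct.cdr3
        for pos in range(len(s)):
            buckets[(len(s), pos, s[:pos] + "*" + s[pos + 1 :])].append(idx)
    edges: set[tuple[int, int]] = set()
    for members in buckets.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if i != j:
                    edges.add((min(i, j), max(i, j)))
    return edges


# ---------------------------------------------------------------------------
# Local similarity (shared enriched motifs)
# ---------------------------------------------------------------------------

def interior_motifs(cdr3: str, k_set: Sequence[int] = (2, 3, 4)) -> set[str]:
    """Deduplicated contiguous k-mers from the CDR3 interior window.

    The window trims three residues from each end (1-based positions 4..L-3);
    a k-mer must lie entirely inside the window.  CDR3s of length <= 6 have an
    empty window and yield no motifs.
    """
    interior = cdr3[3 : max(len(cdr3) - 3, 3)]
    out: set[str] = set()
    for k in k_set:
        for start in range(len(interior) - k + 1):
            out.add(interior[start : start + k])
    return out


def scan_motifs(
    clonotypes: Sequence[Clonotype], k_set: Sequence[int] = (2, 3, 4)
) -> dict[str, set[int]]:
    """Map each interior motif to the set of clonotype indices containing it."""
    motif_map: dict[str, set[int]] = defaultdict(set)
    for idx, ct in enumerate(clonotypes):
        for motif in interior_motifs(ct.cdr3, k_set):
            motif_map[motif].add(idx)
    return dict(motif_map)


def motif_enrichment(
    motif_map: Mapping[str, set[int]],
    n_sample: int,
    reference: Sequence[str],
    k_set: Sequence[int] = (2, 3, 4),
    n_resamples: int = 10000,
    seed: int = 0,
    fold_min: float = 10.0,
    p_max: float = 0.001,
    min_clonotypes: int = 2,
) -> pd.DataFrame:
    """Fold enrichment and resampling probability per shared motif.

    ``sample_freq`` is the fraction of the ``n_sample`` clonotypes containing
    the motif; ``ref_freq`` is the fraction of reference CDR3s containing it
    (floored at ``1/(len(reference)+1)`` when unseen, keeping the fold
    finite).  The probability is estimated by drawing ``n_resamples``
    subsamples of size ``n_sample`` from the reference without replacement and
    counting how often the motif appears at least as many times as observed.
    Only motifs carried by at least ``min_clonotypes`` clonotypes are tested
    (singleton motifs cannot form an edge).
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    n_ref = len(reference)
    if n_ref < n_sample:
        raise ValueError("reference must be at least as large as the sample")
    if n_resamples < 1000 and p_max <= 0.001:
        warnings.warn(
            f"{n_resamples} resamples cannot resolve probabilities near {p_max}",
            stacklevel=2,
        )
    tested = {m: s for m, s in motif_map.items() if len(s) >= min_clonotypes}
    ref_sets = [interior_motifs(seq, k_set) for seq in reference]

    rng = np.random.default_rng(seed)
    # one shared family of subsamples for every motif
    draws = np.empty((n_resamples, n_sample), dtype=np.int64)
    for r in range(n_resamples):
        draws[r] = rng.choice(n_ref, size=n_sample, replace=False)

    rows = []
    floor = 1.0 / (n_ref + 1)
    for motif in sorted(tested):
        obs = len(tested[motif])
        presence = np.fromiter((motif in s for s in ref_sets), dtype=bool, count=n_ref)
        ref_count = int(presence.sum())
        sample_freq = obs / n_sample
        ref_freq = ref_count / n_ref if ref_count > 0 else floor
        fold = sample_freq / ref_freq
        p = float((presence[draws].sum(axis=1) >= obs).mean())
        rows.append(
            {
                "motif": motif,
                "n_clonotypes": obs,
                "sample_freq": sample_freq,
                "ref_count": ref_count,
                "ref_freq": ref_freq,
                "fold": fold,
                "p": p,
                "enriched": bool(fold >= fold_min and p < p_max),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif", "n_clonotypes", "sample_freq", "ref_count",
            "ref_freq", "fold", "p", "enriched",
        ],
    )


def local_similarity_edges(
    motif_map: Mapping[str, set[int]], enriched_motifs: Sequence[str]
) -> set[tuple[int, int]]:
    """Index pairs of clonotypes sharing at least one enriched motif."""
    edges: set[tuple[int, int]] = set()
    for motif in enriched_motifs:
        members = sorted(motif_map.get(motif, ()))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                edges.add((members[a], members[b]))
    return edges


# ---------------------------------------------------------------------------
# Network assembly, modularity, Louvain
# ---------------------------------------------------------------------------

@dataclass
class SpecificityNetwork:
    """Undirected specificity graph over a fixed clonotype node set."""

    clonotypes: list[Clonotype]
    edge_types: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.clonotypes)

    @property
    def m(self) -> int:
        return len(self.edge_types)

    @property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int64)
        for i, j in self.edge_types:
            a[i, j] = a[j, i] = 1
        return a

    @property
    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edge_types:
            k[i] += 1
            k[j] += 1
        return k

    @property
    def network_fraction(self) -> float:
        """Fraction of distinct clonotypes with at least one edge."""
        if self.n_nodes == 0:
            return 0.0
        return float((self.degrees >= 1).sum() / self.n_nodes)

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=list(self.edge_types), directed=False)
        g.vs["cdr3"] = [c.cdr3 for c in self.clonotypes]
        g.vs["v_gene"] = [c.v_gene for c in self.clonotypes]
        g.vs["cell_count"] = [c.cell_count for c in self.clonotypes]
        g.es["type"] = [self.edge_types[e] for e in self.edge_types]
        return g

    def write_graphml(self, path) -> None:
        self.to_igraph().write_graphml(str(path))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "cdr3_a": self.clonotypes[i].cdr3,
                "v_gene_a": self.clonotypes[i].v_gene,
                "cdr3_b": self.clonotypes[j].cdr3,
                "v_gene_b": self.clonotypes[j].v_gene,
                "type": t,
            }
            for (i, j), t in sorted(self.edge_types.items())
        ]
        return pd.DataFrame(rows, columns=["cdr3_a", "v_gene_a", "cdr3_b", "v_gene_b", "type"])


def build_network(
    clonotypes: Sequence[Clonotype],
    global_edges: set[tuple[int, int]],
    local_edges: set[tuple[int, int]],
) -> SpecificityNetwork:
    """Union of global and local edges with parallel edges collapsed.

    An edge present in both sets is typed ``"both"``; self-loops are ignored.
    """
    edge_types: dict[tuple[int, int], str] = {}
    for src, kind in ((global_edges, "global"), (local_edges, "local")):
        for i, j in src:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            prev = edge_types.get(key)
            if prev is None:
                edge_types[key] = kind
            elif prev != kind:
                edge_types[key] = "both"
    return SpecificityNetwork(clonotypes=list(clonotypes), edge_types=edge_types)


def modularity(network, membership: Sequence) -> float:
    """Exact modularity Q of a partition of a binary undirected graph.

    Evaluates the double sum over ordered pairs as
    ``Q = S_A/(2m) - S_k/(2m)^2`` where ``S_A`` is the number of ordered
    within-community adjacent pairs and ``S_k = sum_c (sum_{i in c} k_i)^2``;
    with integer degrees both terms are exact, so the one-community partition
    returns exactly 0.
    """
    A = network.adjacency if isinstance(network, SpecificityNetwork) else np.asarray(network)
    membership = np.asarray(membership)
    if membership.shape[0] != A.shape[0] or np.any(pd.isna(membership)):
        raise ValueError("every node needs exactly one community assignment")
    k = A.sum(axis=1)
    two_m = float(A.sum())
    if two_m < 2:
        raise ValueError("modularity requires at least one edge")
    same = membership[:, None] == membership[None, :]
    s_a = float((A * same).sum())
    codes = pd.factorize(membership)[0]
    s_k = float((np.bincount(codes, weights=k) ** 2).sum())
    return s_a / two_m - s_k / (two_m * two_m)


@dataclass
class CommunityPartition:
    membership: np.ndarray
    q: float


def louvain_partition(
    network: SpecificityNetwork, seed: int = 0, resolution: float = 1.0
) -> CommunityPartition:
    """Louvain community detection (igraph multilevel) with a pinned seed.

    igraph draws its sweep order from Python's ``random`` module; the seed is
    applied locally and the previous RNG state restored.  The returned Q is
    recomputed with :func:`modularity` on the final membership.
    """
    if network.m < 1:
        raise ValueError("Louvain requires at least one edge")
    g = network.to_igraph()
    state = random.getstate()
    random.seed(seed)
    try:
        part = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)
    membership = np.asarray(part.membership)
    return CommunityPartition(membership=membership, q=modularity(network, membership))


# ---------------------------------------------------------------------------
# Repertoire summary
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSummary:
    library: str
    n_clonotypes: int
    network_fraction: float
    expanded_community_modularity: float  # NaN when no qualifying component
    n_expanded_used: int
    n_components_used: int


def expanded_community_modularity(
    network: SpecificityNetwork,
    seed: int = 0,
    n_top: int = 10,
    min_component_size: int = 3,
    resolution: float = 1.0,
) -> RepertoireSummary:
    """Mean Louvain modularity of components housing the expanded clonotypes.

    The ``n_top`` clonotypes are ranked by cell count (ties toward larger
    degree, then lexicographic CDR3).  Every connected component containing at
    least one of them and at least ``min_component_size`` nodes is clustered
    with Louvain and contributes its modularity; the summary is the mean over
    those components and is NaN (flagged by ``n_components_used == 0``) when
    none qualifies.
    """
    degrees = network.degrees
    order = sorted(
        range(network.n_nodes),
        key=lambda i: (-network.clonotypes[i].cell_count, -degrees[i], network.clonotypes[i].cdr3),
    )
    top = set(order[: min(n_top, network.n_nodes)])

    g = ig.Graph(n=network.n_nodes, edges=list(network.edge_types), directed=False)
    comp_membership = np.asarray(g.connected_components().membership)
    qs = []
    for comp_id in np.unique(comp_membership):
        nodes = np.flatnonzero(comp_membership == comp_id)
        if len(nodes) < min_component_size or not top.intersection(nodes):
            continue
        remap = {int(n): i for i, n in enumerate(nodes)}
        sub_edges = {
            (remap[i], remap[j]): t
            for (i, j), t in network.edge_types.items()
            if i in remap and j in remap
        }
        sub = SpecificityNetwork(
            clonotypes=[network.clonotypes[int(n)] for n in nodes], edge_types=sub_edges
        )
        qs.append(louvain_partition(sub, seed=seed, resolution=resolution).q)

    library = network.clonotypes[0].library if network.clonotypes else ""
    return RepertoireSummary(
        library=library,
        n_clonotypes=network.n_nodes,
        network_fraction=network.network_fraction,
        expanded_community_modularity=float(np.mean(qs)) if qs else float("nan"),
        n_expanded_used=len(top),
        n_components_used=len(qs),
    )
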