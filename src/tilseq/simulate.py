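"""Synthetic data generators with planted ground truth.

Three generators emulate the shapes of the study's inputs so every downstream
stage can be exercised without any external download:

* :func:`simulate_counts` — multi-library UMI count matrices with planted cell
  types, marker genes, mitochondrial/ribosomal content and QC-violating cells,
  each violator exceeding exactly one QC threshold.
* :func:`simulate_repertoire` — per-library TCR contig tables with geometric
  clonal expansion and planted specificity groups sharing an interior CDR3
  motif, plus a naive reference repertoire in which every planted motif is
  rare enough that 10-fold enrichment holds by construction.
* :func:`simulate_growth` — per-mouse tumor growth curves with planted
  rejecter / partial-controller / progressor outcomes.

All generators are pure functions of their config (which includes the seed):
rerunning with the same config reproduces identical output, byte for byte
once written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import sc
from .sc import QCThresholds

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Mouse mitochondrial protein-coding gene symbols used for QC-driving genes.
MITO_GENE_NAMES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

VIOLATION_KINDS = ("high_umi", "low_gene", "high_mito", "low_ribo")


class SimulationError(RuntimeError):
    """Raised when a generator cannot satisfy its planted constraints."""


# ===========================================================================
# Count matrices
# ===========================================================================

@dataclass(frozen=True)
class CountSimConfig:
    """Configuration of the planted-cluster UMI count generator.

    Counts are gene-wise negative binomial with lognormal mean heterogeneity;
    marker genes of a cell type have their mean multiplied by
    ``2**marker_log2_effect`` in cells of that type.  Mitochondrial genes use
    mouse ``mt-`` symbols, ribosomal genes ``Rps``/``Rpl`` symbols, with means
    tuned so clean cells sit comfortably inside the QC window; planted
    violators are then constructed to break exactly one rule each.
    """

    n_libraries: int = 4
    cells_per_library: int = 500
    n_genes: int = 2000
    n_cell_types: int = 6
    marker_genes_per_type: int = 17
    marker_log2_effect: float = 3.0
    cell_type_names: tuple[str, ...] | None = None
    mean_log_mu: float = float(np.log(0.4))
    mean_log_sigma: float = 1.3
    marker_mean_log_mu: float = float(np.log(3.0))
    marker_mean_log_sigma: float = 0.5
    nb_dispersion: float = 2.0
    n_mito_genes: int = 13
    mito_mean: float = 8.0
    n_ribo_genes: int = 100
    ribo_mean: float = 6.0
    n_high_umi: int = 3
    n_low_gene: int = 3
    n_high_mito: int = 3
    n_low_ribo: int = 3
    mixing: tuple[tuple[float, ...], ...] | None = None
    n_cell_cycle_genes: int = 20
    proliferating_type: int | None = None
    cc_gene_boost: float = 3.0
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_genes_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("more planted marker genes than genes")
        n_special = (
            self.marker_genes_per_type * self.n_cell_types
            + self.n_mito_genes + self.n_ribo_genes + self.n_cell_cycle_genes
        )
        if n_special > self.n_genes:
            raise ValueError("special gene groups exceed n_genes")
        if self.marker_log2_effect < 0 or self.nb_dispersion <= 0:
            raise ValueError("effects and dispersion must be positive")
        if self.n_violators >= self.cells_per_library:
            raise ValueError("more planted violators than cells")
        if self.mixing is not None:
            if len(self.mixing) != self.n_libraries:
                raise ValueError("mixing needs one row per library")
            for row in self.mixing:
                if len(row) != self.n_cell_types or abs(sum(row) - 1.0) > 1e-9:
                    raise ValueError("mixing rows must sum to 1 over cell types")

    @property
    def n_violators(self) -> int:
        return self.n_high_umi + self.n_low_gene + self.n_high_mito + self.n_low_ribo

    @property
    def type_names(self) -> tuple[str, ...]:
        if self.cell_type_names is not None:
            return self.cell_type_names
        defaults = ("CD8 T", "CD4 T", "NKC", "macrophage", "DC", "neutrophil")
        if self.n_cell_types <= len(defaults):
            return defaults[: self.n_cell_types]
        return defaults + tuple(f"type{i}" for i in range(len(defaults), self.n_cell_types))

    @property
    def library_ids(self) -> tuple[str, ...]:
        return tuple(f"lib{i + 1}" for i in range(self.n_libraries))


@dataclass
class CountTruth:
    """Planted truth of :func:`simulate_counts`."""

    obs: pd.DataFrame                # per cell: library, cell_type, qc_flag
    marker_genes: dict               # cell type name -> marker gene symbols
    cc_genes: list                   # simulated cell-cycle gene symbols
    mixing: pd.DataFrame             # library x cell type proportions
    library_totals: dict             # library -> total UMI count in its matrix


def _gene_symbols(cfg: CountSimConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Assemble gene symbols: mito, ribo, cell-cycle, markers, background."""
    mito = [MITO_GENE_NAMES[i] if i < len(MITO_GENE_NAMES) else f"mt-g{i + 1}"
            for i in range(cfg.n_mito_genes)]
    half = cfg.n_ribo_genes // 2
    ribo = [f"Rps{i + 1}" for i in range(half)] + [f"Rpl{i + 1}" for i in range(cfg.n_ribo_genes - half)]
    cc_pool = [g for g in sc.load_cell_cycle_genes()]
    cc = cc_pool[: cfg.n_cell_cycle_genes]
    cc += [f"Cc{i}" for i in range(len(cc), cfg.n_cell_cycle_genes)]

    used = set(mito) | set(ribo) | set(cc)
    markers: dict[str, list[str]] = {}
    for t, name in enumerate(cfg.type_names):
        panel = [g for g in sc.MARKER_PANELS.get(name, ()) if g not in used]
        symbols = panel[: cfg.marker_genes_per_type]
        j = 0
        while len(symbols) < cfg.marker_genes_per_type:
            cand = f"Mk{t}.{j}"
            if cand not in used:
                symbols.append(cand)
            j += 1
        markers[name] = symbols
        used.update(symbols)

    n_background = cfg.n_genes - len(mito) - len(ribo) - len(cc) - sum(
        len(v) for v in markers.values()
    )
    background = [f"Gene{i + 1:04d}" for i in range(n_background)]
    symbols = mito + ribo + cc + [g for name in cfg.type_names for g in markers[name]] + background
    assert len(symbols) == cfg.n_genes and len(set(symbols)) == cfg.n_genes
    return symbols, markers, cc


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    return rng.negative_binomial(dispersion, dispersion / (dispersion + mean))


def _single_metrics(counts: np.ndarray, symbols: Sequence[str], thresholds: QCThresholds):
    metrics = sc.compute_qc_metrics(counts[None, :], symbols)
    return sc.qc_violations(metrics, thresholds).iloc[0]


def _make_violator(
    rng: np.random.Generator,
    kind: str,
    clean: np.ndarray,
    symbols: Sequence[str],
    mito_mask: np.ndarray,
    ribo_mask: np.ndarray,
    t: QCThresholds,
) -> np.ndarray | None:
    """Turn a clean cell into a cell violating exactly ``kind``; None on failure."""
    c = clean.astype(np.int64).copy()
    total = int(c.sum())
    if kind == "high_umi":
        c *= int(np.ceil((t.max_total_umis + 1) / total))
    elif kind == "low_gene":
        target = t.min_genes - 1 - int(rng.integers(0, max(1, t.min_genes // 12)))
        expressed = np.flatnonzero(c > 0)
        removable = [g for g in expressed if not (mito_mask[g] or ribo_mask[g])]
        n_remove = len(expressed) - target
        if n_remove <= 0 or n_remove > len(removable):
            return None
        order = sorted(removable, key=lambda g: (c[g], g))
        c[order[:n_remove]] = 0
    elif kind == "high_mito":
        m = int(c[mito_mask].sum())
        if m == 0:
            return None
        other = total - m
        tau = min(0.9, 1.5 * t.max_mito)
        c[mito_mask] = np.round(c[mito_mask] * (tau / (1 - tau)) * other / m).astype(np.int64)
    elif kind == "low_ribo":
        r = int(c[ribo_mask].sum())
        if r == 0:
            return None
        other = total - r
        tau = t.min_ribo / 2
        c[ribo_mask] = np.floor(c[ribo_mask] * (tau / (1 - tau)) * other / r).astype(np.int64)
    else:  # pragma: no cover
        raise ValueError(kind)
    violations = _single_metrics(c, symbols, t)
    if violations[kind] and violations.sum() == 1:
        return c
    return None


def simulate_counts(cfg: CountSimConfig) -> tuple[dict[str, ad.AnnData], CountTruth]:
    """Generate one AnnData per library plus the planted truth."""
    rng = np.random.default_rng(cfg.seed)
    symbols, markers, cc_genes = _gene_symbols(cfg)
    col = {g: i for i, g in enumerate(symbols)}
    mito_mask = np.array([g.startswith("mt-") for g in symbols])
    ribo_mask = np.array([g.startswith(("Rps", "Rpl")) for g in symbols])
    cc_cols = np.array([col[g] for g in cc_genes], dtype=int)

    base = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, cfg.n_genes)
    base[mito_mask] = rng.lognormal(np.log(cfg.mito_mean), 0.3, mito_mask.sum())
    base[ribo_mask] = rng.lognormal(np.log(cfg.ribo_mean), 0.3, ribo_mask.sum())
    marker_cols = {}
    for name in cfg.type_names:
        idx = np.array([col[g] for g in markers[name]], dtype=int)
        base[idx] = rng.lognormal(cfg.marker_mean_log_mu, cfg.marker_mean_log_sigma, len(idx))
        marker_cols[name] = idx

    type_means = np.tile(base, (cfg.n_cell_types, 1))
    for ti, name in enumerate(cfg.type_names):
        type_means[ti, marker_cols[name]] *= 2.0 ** cfg.marker_log2_effect
        if cfg.proliferating_type == ti:
            type_means[ti, cc_cols] *= cfg.cc_gene_boost

    mixing = (
        np.asarray(cfg.mixing, dtype=float)
        if cfg.mixing is not None
        else np.full((cfg.n_libraries, cfg.n_cell_types), 1.0 / cfg.n_cell_types)
    )

    def sample_clean(types: np.ndarray) -> np.ndarray:
        counts = _nb_sample(rng, type_means[types], cfg.nb_dispersion)
        for _ in range(200):
            metrics = sc.compute_qc_metrics(counts, symbols)
            bad = np.flatnonzero(sc.qc_violations(metrics, cfg.thresholds).any(axis=1).to_numpy())
            if bad.size == 0:
                return counts
            counts[bad] = _nb_sample(rng, type_means[types[bad]], cfg.nb_dispersion)
        raise SimulationError("could not sample QC-clean cells; widen thresholds or lower means")

    adatas: dict[str, ad.AnnData] = {}
    obs_frames = []
    library_totals = {}
    kinds = (
        ["high_umi"] * cfg.n_high_umi + ["low_gene"] * cfg.n_low_gene
        + ["high_mito"] * cfg.n_high_mito + ["low_ribo"] * cfg.n_low_ribo
    )
    for li, lib in enumerate(cfg.library_ids):
        n_clean = cfg.cells_per_library - cfg.n_violators
        types = rng.choice(cfg.n_cell_types, size=n_clean, p=mixing[li])
        counts = sample_clean(types)

        v_rows, v_types = [], []
        for kind in kinds:
            for _ in range(50):
                v_type = rng.choice(cfg.n_cell_types, p=mixing[li])
                template = sample_clean(np.array([v_type]))[0]
                made = _make_violator(rng, kind, template, symbols, mito_mask, ribo_mask, cfg.thresholds)
                if made is not None:
                    v_rows.append(made)
                    v_types.append(v_type)
                    break
            else:
                raise SimulationError(f"could not construct a {kind} violator")

        all_counts = np.vstack([counts] + [r[None, :] for r in v_rows]) if v_rows else counts
        flags = ["clean"] * n_clean + kinds
        all_types = np.concatenate([types, np.array(v_types, dtype=int)]) if v_types else types
        perm = rng.permutation(all_counts.shape[0])
        all_counts, all_types = all_counts[perm], all_types[perm]
        flags = [flags[i] for i in perm]

        barcodes = [f"c{i + 1:04d}" for i in range(all_counts.shape[0])]
        obs = pd.DataFrame(
            {
                "library": lib,
                "barcode": barcodes,
                "cell_type": [cfg.type_names[t] for t in all_types],
                "qc_flag": flags,
            },
            index=pd.Index([f"{lib}:{bc}" for bc in barcodes]),
        )
        var = pd.DataFrame(
            {"gene_id": [f"G{i + 1:06d}" for i in range(cfg.n_genes)],
             "feature_type": "Gene Expression"},
            index=pd.Index(symbols, name="gene_symbol"),
        )
        adatas[lib] = ad.AnnData(X=sp.csr_matrix(all_counts), obs=obs, var=var)
        obs_frames.append(obs)
        library_totals[lib] = int(all_counts.sum())

    truth = CountTruth(
        obs=pd.concat(obs_frames),
        marker_genes=markers,
        cc_genes=cc_genes,
        mixing=pd.DataFrame(mixing, index=list(cfg.library_ids), columns=list(cfg.type_names)),
        library_totals=library_totals,
    )
    return adatas, truth


# ===========================================================================
# TCR repertoires
# ===========================================================================

@dataclass(frozen=True)
class RepertoireSimConfig:
    """Configuration of the planted specificity-group repertoire generator.

    CDR3s are length 12-18 with fixed first residue C and last residue F;
    group motifs are implanted only in the interior window (trimming three
    residues from each end) so the motif scanner is guaranteed to see them.
    Clone sizes are geometric with parameter ``p_clone``.  Consecutive groups
    are joined with probability ``bridge_probability`` by implanting the
    previous group's motif into one member, which chains specificity groups
    into larger components with internal community structure.
    """

    library_ids: tuple[str, ...] = ("lib1", "lib2", "lib3")
    n_clonotypes: int = 60
    p_clone: float = 0.4
    n_specificity_groups: int = 8
    group_size_min: int = 3
    group_size_max: int = 5
    motif_length: int = 3
    cdr3_len_min: int = 12
    cdr3_len_max: int = 18
    bridge_probability: float = 0.5
    reference_size: int = 1000
    alpha_fraction: float = 0.1
    nonproductive_fraction: float = 0.05
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_length not in (2, 3, 4):
            raise ValueError("motif_length must be one of {2, 3, 4}")
        if self.motif_length > self.cdr3_len_min - 6:
            raise ValueError("motif must fit the interior window of the shortest CDR3")
        if self.group_size_min < 2:
            raise ValueError("specificity groups need at least 2 members")
        if self.n_specificity_groups * self.group_size_max > self.n_clonotypes:
            raise ValueError("planted groups exceed the clonotype budget")
        if not 0 < self.p_clone <= 1:
            raise ValueError("p_clone must lie in (0, 1]")
        if self.reference_size < self.n_clonotypes:
            raise ValueError("reference must be at least sample-sized")


@dataclass
class RepertoireTruth:
    """Planted truth of :func:`simulate_repertoire` for one library set."""

    clonotypes: dict        # library -> DataFrame(cdr3, v_gene, group, cell_count)
    group_motifs: dict      # library -> {group label: motif}


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    middle = "".join(rng.choice(list(AMINO_ACIDS), size=length - 2))
    return "C" + middle + "F"


def _implant(rng: np.random.Generator, cdr3: str, motif: str, avoid: tuple[int, int] | None = None) -> tuple[str, tuple[int, int]] | None:
    """Place ``motif`` fully inside the interior window; avoid an occupied span."""
    L, k = len(cdr3), len(motif)
    starts = [s for s in range(3, L - 3 - k + 1)
              if avoid is None or s + k <= avoid[0] or s >= avoid[1]]
    if not starts:
        return None
    s = int(rng.choice(starts))
    return cdr3[:s] + motif + cdr3[s + k:], (s, s + k)


def simulate_repertoire(
    cfg: RepertoireSimConfig,
) -> tuple[dict[str, pd.DataFrame], list[str], RepertoireTruth]:
    """Generate per-library contig tables, a naive reference, and the truth."""
    rng = np.random.default_rng(cfg.seed)
    from .tcr import interior_motifs  # local import avoids a cycle

    k_set = (cfg.motif_length,)
    truth_clono: dict[str, pd.DataFrame] = {}
    truth_motifs: dict[str, dict[str, str]] = {}
    contig_tables: dict[str, pd.DataFrame] = {}
    all_motif_freq: dict[str, float] = {}

    for lib in cfg.library_ids:
        sizes = rng.integers(cfg.group_size_min, cfg.group_size_max + 1, cfg.n_specificity_groups)
        motifs: list[str] = []
        while len(motifs) < cfg.n_specificity_groups:
            m = "".join(rng.choice(list(AMINO_ACIDS), size=cfg.motif_length))
            if m not in motifs:
                motifs.append(m)

        records = []
        seen_cdr3: set[str] = set()

        def fresh_cdr3(required: list[str]) -> str:
            """A unique CDR3 carrying exactly the required motifs, no others."""
            forbidden = [m for m in motifs if m not in required]
            for _ in range(cfg.max_retries):
                length = int(rng.integers(cfg.cdr3_len_min, cfg.cdr3_len_max + 1))
                s = _random_cdr3(rng, length)
                span = None
                ok = True
                for m in required:
                    placed = _implant(rng, s, m, avoid=span)
                    if placed is None:
                        ok = False
                        break
                    s, span = placed
                if not ok or s in seen_cdr3:
                    continue
                inter = interior_motifs(s, k_set)
                if required and not all(m in inter for m in required):
                    continue
                if any(m in inter for m in forbidden):
                    continue
                seen_cdr3.add(s)
                return s
            raise SimulationError("could not draw a CDR3 satisfying motif constraints")

        for gi, (size, motif) in enumerate(zip(sizes, motifs)):
            for member in range(size):
                required = [motif]
                # bridge: first member of group gi also carries group gi-1's motif
                if member == 0 and gi > 0 and rng.random() < cfg.bridge_probability:
                    required = [motif, motifs[gi - 1]]
                records.append(
                    {"cdr3": fresh_cdr3(required),
                     "v_gene": f"TRBV{int(rng.integers(1, 20))}",
                     "group": f"g{gi}",
                     "bridge": len(required) > 1}
                )
        while len(records) < cfg.n_clonotypes:
            records.append(
                {"cdr3": fresh_cdr3([]), "v_gene": f"TRBV{int(rng.integers(1, 20))}",
                 "group": "none", "bridge": False}
            )
        table = pd.DataFrame(records)
        table["cell_count"] = rng.geometric(cfg.p_clone, size=len(table))
        truth_clono[lib] = table
        truth_motifs[lib] = {f"g{gi}": m for gi, m in enumerate(motifs)}
        for gi, m in enumerate(motifs):
            freq = int(sizes[gi]) / cfg.n_clonotypes
            all_motif_freq[m] = min(freq, all_motif_freq.get(m, 1.0))

        rows = []
        counter = 0
        for rec in table.itertuples():
            for _ in range(int(rec.cell_count)):
                counter += 1
                bc = f"bc{counter:05d}"
                rows.append(
                    {"barcode": bc, "chain": "TRB", "v_gene": rec.v_gene, "j_gene": "TRBJ1-1",
                     "cdr3": rec.cdr3, "productive": True, "high_confidence": True,
                     "umis": int(rng.integers(2, 9)), "library": lib}
                )
                if rng.random() < cfg.alpha_fraction:
                    rows.append(
                        {"barcode": bc, "chain": "TRA", "v_gene": "TRAV1", "j_gene": "TRAJ1",
                         "cdr3": _random_cdr3(rng, 13), "productive": True,
                         "high_confidence": True, "umis": int(rng.integers(1, 5)), "library": lib}
                    )
                if rng.random() < cfg.nonproductive_fraction:
                    rows.append(
                        {"barcode": bc, "chain": "TRB", "v_gene": rec.v_gene, "j_gene": "TRBJ1-1",
                         "cdr3": _random_cdr3(rng, 12), "productive": False,
                         "high_confidence": True, "umis": 1, "library": lib}
                    )
        contig_tables[lib] = pd.DataFrame(rows)

    # Naive reference: every planted motif at most 1/10 of its smallest
    # in-sample frequency, so 10-fold enrichment holds by construction.
    caps = {m: int(np.floor(cfg.reference_size * f / 10.0)) for m, f in all_motif_freq.items()}
    reference = [
        _random_cdr3(rng, int(rng.integers(cfg.cdr3_len_min, cfg.cdr3_len_max + 1)))
        for _ in range(cfg.reference_size)
    ]
    for _ in range(cfg.max_retries):
        counts = {m: 0 for m in caps}
        over: set[str] = set()
        for seq in reference:
            inter = interior_motifs(seq, k_set)
            for m in caps:
                if m in inter:
                    counts[m] += 1
        over = {m for m, c in counts.items() if c > caps[m]}
        if not over:
            break
        for i, seq in enumerate(reference):
            if interior_motifs(seq, k_set) & over:
                reference[i] = _random_cdr3(
                    rng, int(rng.integers(cfg.cdr3_len_min, cfg.cdr3_len_max + 1))
                )
    else:
        raise SimulationError("could not build a reference respecting motif caps")

    truth = RepertoireTruth(clonotypes=truth_clono, group_motifs=truth_motifs)
    return contig_tables, reference, truth


# ===========================================================================
# Tumor growth
# ===========================================================================

@dataclass(frozen=True)
class GrowthSimConfig:
    """Configuration of the tumor-growth curve generator.

    Progressors grow exponentially at ``growth_rate`` (per day) from
    ``initial_area`` (mm^2).  Rejecters grow until ``rejection_day`` and then
    shrink at ``rejection_decay`` per day; areas below ``detection_floor``
    (the palpation limit) are recorded as 0, so complete rejecters end at
    exactly 0 by the final day.  Partial controllers follow the same shape but
    plateau at ``partial_plateau`` instead of clearing.  Noise is
    multiplicative lognormal with sd ``noise_sd`` (zeros stay zero).
    """

    group_fractions: tuple[tuple[float, float, float], ...] = ((1.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    group_ids: tuple[str, ...] | None = None
    mice_per_group: int = 5
    days: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
    initial_area: float = 4.0
    growth_rate: float = 0.15
    rejection_day: float = 9.0
    rejection_decay: float = 0.5
    partial_plateau: float = 4.0
    detection_floor: float = 0.25
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError("empty day grid")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly ascending")
        for row in self.group_fractions:
            if len(row) != 3 or abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("group fractions (complete, partial, progression) must sum to 1")
        if self.group_ids is not None and len(self.group_ids) != len(self.group_fractions):
            raise ValueError("group_ids must match group_fractions")

    @property
    def resolved_group_ids(self) -> tuple[str, ...]:
        if self.group_ids is not None:
            return self.group_ids
        return tuple(f"group{i + 1}" for i in range(len(self.group_fractions)))


@dataclass
class GrowthTruth:
    outcomes: pd.DataFrame  # per mouse: group, mouse, outcome


def _outcome_counts(fractions: tuple[float, float, float], n: int) -> list[int]:
    """Largest-remainder allocation of n mice to the three outcomes."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[order[i % 3]] += 1
    return counts


def _curve(cfg: GrowthSimConfig, outcome: str, days: np.ndarray) -> np.ndarray:
    grown = cfg.initial_area * np.exp(cfg.growth_rate * np.minimum(days, cfg.rejection_day))
    if outcome == "progression":
        return cfg.initial_area * np.exp(cfg.growth_rate * days)
    decayed = grown * np.exp(-cfg.rejection_decay * np.maximum(days - cfg.rejection_day, 0.0))
    if outcome == "partial_control":
        return np.maximum(decayed, cfg.partial_plateau)
    return decayed  # complete rejection; floored to 0 after noise


def simulate_growth(cfg: GrowthSimConfig) -> tuple[pd.DataFrame, GrowthTruth]:
    """Generate a (group, mouse, day, area) table plus planted outcomes."""
    rng = np.random.default_rng(cfg.seed)
    days = np.asarray(cfg.days, dtype=float)
    rows, outcome_rows = [], []
    for gi, gid in enumerate(cfg.resolved_group_ids):
        counts = _outcome_counts(cfg.group_fractions[gi], cfg.mice_per_group)
        planned = (
            ["complete_rejection"] * counts[0]
            + ["partial_control"] * counts[1]
            + ["progression"] * counts[2]
        )
        for mi, outcome in enumerate(planned):
            mouse = f"{gid}-m{mi + 1}"
            areas = _curve(cfg, outcome, days)
            if cfg.noise_sd > 0:
                areas = areas * rng.lognormal(0.0, cfg.noise_sd, size=len(days))
            areas = np.where(areas < cfg.detection_floor, 0.0, areas)
            if outcome == "complete_rejection" and areas[-1] > 0:
                raise SimulationError(
                    "rejection_decay too weak: complete rejecter does not clear by the final day"
                )
            outcome_rows.append({"group": gid, "mouse": mouse, "outcome": outcome})
            for d, a in zip(days, areas):
                rows.append({"group": gid, "mouse": mouse, "day": d, "area": round(float(a), 3)})
    table = pd.DataFrame(rows, columns=["group", "mouse", "day", "area"])
    return table, GrowthTruth(outcomes=pd.DataFrame(outcome_rows))
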