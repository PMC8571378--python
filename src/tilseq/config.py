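"""Pipeline configuration.

A single flat configuration object carries every tunable threshold of the
analysis: QC cutoffs, feature-selection size, cluster counts, differential
expression thresholds, TCR motif-enrichment parameters, bootstrap settings and
the random seed.  It round-trips through YAML so a run is fully described by
one human-editable file plus the input data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its legal range."""


@dataclass
class PipelineConfig:
    """Flat bag of analysis parameters with validated defaults.

    QC thresholds follow the convention that a cell is *excluded* when any of
    the strict comparisons fires: total UMIs over ``qc_max_total_umis``, fewer
    than ``qc_min_genes`` or more than ``qc_max_genes`` expressed genes,
    mitochondrial fraction higher than ``qc_max_mito`` or ribosomal fraction
    lower than ``qc_min_ribo``.
    """

    # --- cell quality control -------------------------------------------------
    qc_max_total_umis: int = 30000
    qc_min_genes: int = 500
    qc_max_genes: int = 5000
    qc_max_mito: float = 0.10
    qc_min_ribo: float = 0.05
    mito_prefix: str = "mt-"
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")

    # --- feature selection / clustering --------------------------------------
    n_top_genes: int = 1500
    n_major_clusters: int = 2
    n_lymphoid_clusters: int = 6
    n_myeloid_clusters: int = 9
    n_tcell_clusters: int = 7

    # --- differential expression ----------------------------------------------
    # Annotation thresholds (raw p paired with an effect-size cutoff); the
    # reporting set (1.5-fold, p<0.05) is exposed separately.
    de_p_threshold: float = 0.01
    de_lfc_threshold: float = 1.0
    report_p_threshold: float = 0.05
    report_lfc_threshold: float = math.log2(1.5)

    # --- cell-cycle screen ------------------------------------------------------
    cc_flag_ratio: float = 2.0

    # --- TCR specificity networks ----------------------------------------------
    motif_lengths: tuple[int, ...] = (2, 3, 4)
    enrichment_fold: float = 10.0
    enrichment_p: float = 0.001
    n_resamples: int = 10000
    n_expanded_clonotypes: int = 10
    louvain_resolution: float = 1.0

    # --- library hierarchy -------------------------------------------------------
    bootstrap_replicates: int = 200

    # --- tumor growth scoring ----------------------------------------------------
    complete_threshold: float = 0.0
    partial_threshold: float = 10.0
    partial_weight: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        if self.qc_min_genes >= self.qc_max_genes:
            raise ConfigError("qc_min_genes must be < qc_max_genes")
        for name in ("qc_max_mito", "qc_min_ribo"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.n_top_genes <= 0:
            raise ConfigError("n_top_genes must be positive")
        if not 0.0 < self.de_p_threshold <= 1.0:
            raise ConfigError("de_p_threshold must lie in (0, 1]")
        if self.enrichment_fold <= 0:
            raise ConfigError("enrichment_fold must be positive")
        if not 0.0 < self.enrichment_p < 1.0:
            raise ConfigError("enrichment_p must lie in (0, 1)")
        if any(k not in (2, 3, 4) for k in self.motif_lengths):
            raise ConfigError("motif_lengths restricted to {2, 3, 4}")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        if not 0.0 <= self.partial_weight <= 1.0:
            raise ConfigError("partial_weight must lie in [0, 1]")
        if not 0.0 <= self.complete_threshold < self.partial_threshold:
            raise ConfigError("require 0 <= complete_threshold < partial_threshold")

    # --- YAML round trip ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ribo_prefixes"] = list(self.ribo_prefixes)
        d["motif_lengths"] = list(self.motif_lengths)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("ribo_prefixes", "motif_lengths"):
            if key in d and isinstance(d[key], Sequence) and not isinstance(d[key], str):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)
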