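"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices use the Cell Ranger v3 triplet layout (MatrixMarket
``matrix.mtx`` of genes x cells, ``features.tsv`` with gene id / symbol /
feature type, ``barcodes.tsv``), TCR contigs use the 10x
``filtered_contig_annotations.csv`` dialect, and tumor growth tables are plain
CSV with one row per (group, mouse, day) measurement.  All readers are
gzip-tolerant: a ``.gz`` suffix on any path is handled transparently.

In memory, expression data lives in an :class:`anndata.AnnData` with cells as
observations and genes as variables; ``obs["library"]`` records the library of
origin of every cell.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def _open(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Cell Ranger count matrix triplet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrixFiles:
    """Paths of one library's count-matrix triplet plus its label."""

    matrix_path: Path
    features_path: Path
    barcodes_path: Path
    library_id: str

    @classmethod
    def in_dir(cls, directory: str | Path, library_id: str | None = None) -> "CountMatrixFiles":
        """Locate the conventional triplet filenames inside ``directory``."""
        directory = Path(directory)

        def find(stem: str) -> Path:
            for name in (stem, stem + ".gz"):
                p = directory / name
                if p.exists():
                    return p
            raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")

        return cls(
            matrix_path=find("matrix.mtx"),
            features_path=find("features.tsv"),
            barcodes_path=find("barcodes.tsv"),
            library_id=library_id or directory.name,
        )


def read_count_matrix(files: CountMatrixFiles) -> ad.AnnData:
    """Read one library's triplet into an AnnData (cells x genes).

    The MatrixMarket file stores genes as rows and cells as columns with
    1-based coordinate indices; entries must be non-negative integers and the
    declared dimensions must match the lengths of the features and barcodes
    files.
    """
    for p in (files.matrix_path, files.features_path, files.barcodes_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        with _open(files.matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except ValueError as exc:
        raise FormatError(f"invalid MatrixMarket file {files.matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
        raise FormatError("count matrix entries must be non-negative integers")

    features = pd.read_csv(
        files.features_path, sep="\t", header=None,
        names=["gene_id", "gene_symbol", "feature_type"], dtype=str,
    )
    barcodes = pd.read_csv(files.barcodes_path, sep="\t", header=None, names=["barcode"], dtype=str)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix declares {mat.shape} but features/barcodes have "
            f"({len(features)}, {len(barcodes)}) entries"
        )
    if barcodes["barcode"].duplicated().any():
        raise FormatError("duplicate barcodes within a library")

    adata = ad.AnnData(
        X=sp.csr_matrix(mat.T, dtype=np.int64),
        obs=pd.DataFrame({"library": files.library_id}, index=barcodes["barcode"].to_numpy()),
        var=features.set_index("gene_symbol"),
    )
    adata.obs_names = [f"{files.library_id}:{bc}" for bc in barcodes["barcode"]]
    adata.obs["barcode"] = barcodes["barcode"].to_numpy()
    return adata


def write_count_matrix(adata: ad.AnnData, directory: str | Path) -> CountMatrixFiles:
    """Write an AnnData back to the uncompressed triplet layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = CountMatrixFiles(
        matrix_path=directory / "matrix.mtx",
        features_path=directory / "features.tsv",
        barcodes_path=directory / "barcodes.tsv",
        library_id=str(adata.obs["library"].iloc[0]) if "library" in adata.obs else directory.name,
    )
    mat = sp.coo_matrix(adata.X.T)
    scipy.io.mmwrite(str(files.matrix_path), mat, field="integer")
    gene_ids = (
        adata.var["gene_id"]
        if "gene_id" in adata.var
        else pd.Series(adata.var_names, index=adata.var_names)
    )
    feature_type = (
        adata.var["feature_type"]
        if "feature_type" in adata.var
        else pd.Series("Gene Expression", index=adata.var_names)
    )
    pd.DataFrame(
        {"gene_id": gene_ids.to_numpy(), "gene_symbol": adata.var_names, "feature_type": feature_type.to_numpy()}
    ).to_csv(files.features_path, sep="\t", header=False, index=False)
    barcodes = adata.obs["barcode"] if "barcode" in adata.obs else pd.Series(adata.obs_names)
    barcodes.to_csv(files.barcodes_path, sep="\t", header=False, index=False)
    return files


def concat_libraries(adatas: Iterable[ad.AnnData]) -> ad.AnnData:
    """Pool per-library AnnDatas on a shared gene space."""
    adatas = list(adatas)
    pooled = ad.concat(adatas, join="outer", merge="first", fill_value=0)
    pooled.X = sp.csr_matrix(pooled.X)
    return pooled


# ---------------------------------------------------------------------------
# 10x filtered contig annotations
# ---------------------------------------------------------------------------

CONTIG_COLUMNS = ("barcode", "chain", "v_gene", "j_gene", "cdr3", "productive", "high_confidence", "umis")

_TRUE_STRINGS = {"true", "t", "yes", "1"}


def _as_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin(_TRUE_STRINGS)


@dataclass(frozen=True)
class ContigFilters:
    """Row filters applied when loading contig tables.

    Defaults keep productive, high-confidence TRB contigs only; when more than
    one TRB contig survives for a barcode the one with the highest UMI count is
    kept (ties broken by the lexicographically smallest CDR3).
    """

    productive_only: bool = True
    high_confidence_only: bool = True
    beta_only: bool = True


def read_contigs(
    path: str | Path,
    filters: ContigFilters = ContigFilters(),
    library_id: str | None = None,
) -> pd.DataFrame:
    """Load and filter a ``filtered_contig_annotations.csv``-style table."""
    with _open(path) as fh:
        df = pd.read_csv(fh, dtype={"barcode": str, "chain": str, "cdr3": str})
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table missing required columns: {missing}")
    if (pd.to_numeric(df["umis"], errors="coerce") < 0).any():
        raise FormatError("umis must be non-negative")

    df = df.copy()
    df["productive"] = _as_bool(df["productive"])
    df["high_confidence"] = _as_bool(df["high_confidence"])
    if filters.productive_only:
        df = df[df["productive"]]
    if filters.high_confidence_only:
        df = df[df["high_confidence"]]
    if filters.beta_only:
        df = df[df["chain"] == "TRB"]
    # one contig per barcode: max UMIs, ties -> lexicographically smallest CDR3
    df = df.sort_values(["barcode", "umis", "cdr3"], ascending=[True, False, True], kind="stable")
    df = df.drop_duplicates(subset="barcode", keep="first").reset_index(drop=True)
    if "library" not in df.columns:
        df["library"] = library_id if library_id is not None else Path(path).stem
    return df


def write_contigs(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tumor growth tables
# ---------------------------------------------------------------------------

GROWTH_COLUMNS = ("group", "mouse", "day", "area")


def read_growth(path: str | Path) -> pd.DataFrame:
    """Read a per-mouse tumor growth CSV (group, mouse, day, area)."""
    with _open(path) as fh:
        df = pd.read_csv(fh, dtype={"group": str, "mouse": str})
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"growth table missing required columns: {missing}")
    if (df["area"] < 0).any():
        raise FormatError("tumor areas must be non-negative")
    if (df["day"] < 0).any():
        raise FormatError("days must be non-negative")
    for (_, mouse), sub in df.groupby(["group", "mouse"], sort=False):
        if not sub["day"].is_monotonic_increasing or sub["day"].duplicated().any():
            raise FormatError(f"days must be strictly increasing within mouse {mouse!r}")
    return df


def write_growth(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plain-text helpers
# ---------------------------------------------------------------------------

def read_lines(path: str | Path) -> list[str]:
    """Newline-delimited strings (e.g. gene lists, CDR3 reference repertoires)."""
    with _open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_lines(items: Iterable[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{x}\n" for x in items))
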