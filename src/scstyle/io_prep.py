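"""Readers, writers and preprocessing for multi-batch scRNA-seq matrices.

Supported formats: 10x-style Matrix Market triplet directories
(``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``),
dense CSV/TSV with cells in rows, and ``.h5ad`` annotated matrices.
Preprocessing follows the common pipeline for adversarial integration:
library-size / mitochondrial QC, log-TPM-like transform, restriction to
genes detected in every batch, per-batch highly-variable-gene selection,
and a seeded random partition of the gene list for whole-transcriptome
correction (one independent corrector network per chunk).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import LOG_TPM, RAW_COUNTS, ExpressionSet


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _read_labels(source, cell_ids: np.ndarray, what: str) -> np.ndarray:
    """Resolve a label source (array-like, scalar, or 2-column TSV path)."""
    if source is None:
        return None
    if isinstance(source, (str, os.PathLike)) and Path(source).exists():
        df = pd.read_csv(source, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
        mapping = dict(zip(df["cell_id"], df["label"]))
        missing = [c for c in cell_ids if str(c) not in mapping]
        if missing:
            raise ValueError(f"{what} file lacks labels for {len(missing)} cells, e.g. {missing[:3]}")
        return np.array([mapping[str(c)] for c in cell_ids], dtype=object)
    if np.isscalar(source):
        return np.full(len(cell_ids), source, dtype=object)
    arr = np.asarray(source, dtype=object)
    if len(arr) != len(cell_ids):
        raise ValueError(f"{what}: {len(arr)} labels for {len(cell_ids)} cells")
    return arr


def load_matrix(path, fmt: str, batch_labels=None, celltype_labels=None,
                batch_key: str = "batch", celltype_key: str = "celltype") -> ExpressionSet:
    """Load one batch (or a labelled multi-batch file) as raw counts.

    Parameters
    ----------
    path:
        File or directory to read.
    fmt:
        One of ``"mtx_dir"``, ``"csv"``, ``"tsv"``, ``"h5"``.
    batch_labels:
        Per-cell labels, a single batch name, or a path to a two-column
        (cell_id, label) TSV. For ``h5`` the ``batch_key`` obs column is
        used when this is omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")

    if fmt == "mtx_dir":
        matrix, cells, genes = _load_mtx_dir(path)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        matrix = df.to_numpy(dtype=float)
        cells = df.index.to_numpy(dtype=object)
        genes = df.columns.to_numpy(dtype=object)
    elif fmt == "h5":
        import anndata

        ad = anndata.read_h5ad(path)
        es = ExpressionSet.from_anndata(ad, batch_key=batch_key, celltype_key=celltype_key) \
            if batch_key in ad.obs else None
        if es is not None and batch_labels is None:
            return es
        X = ad.X if isinstance(ad.X, np.ndarray) else ad.X.toarray()
        matrix, cells, genes = np.asarray(X, float), ad.obs_names.to_numpy(), ad.var_names.to_numpy()
    else:
        raise ValueError(f"unknown format {fmt!r}; expected mtx_dir, csv, tsv or h5")

    if len(set(cells)) != len(cells):
        raise ValueError(f"duplicate cell ids in {path}")
    b = _read_labels(batch_labels, cells, "batch labels")
    if b is None:
        b = np.full(len(cells), path.stem, dtype=object)
    ct = _read_labels(celltype_labels, cells, "cell-type labels")
    return ExpressionSet(matrix, cells, genes, b, ct, units=RAW_COUNTS)


def _load_mtx_dir(path: Path):
    """Read a 10x triplet directory; matrix.mtx stores genes x cells."""
    mtx = path / "matrix.mtx"
    feats = path / "features.tsv"
    if not feats.exists():
        feats = path / "genes.tsv"
    barcodes = path / "barcodes.tsv"
    for f in (mtx, feats, barcodes):
        if not f.exists():
            raise FileNotFoundError(f"triplet directory {path} is missing {f.name}")
    M = scipy.io.mmread(mtx)
    genes = pd.read_csv(feats, sep="\t", header=None)[0].to_numpy(dtype=object)
    cells = pd.read_csv(barcodes, sep="\t", header=None)[0].to_numpy(dtype=object)
    dense = np.asarray(M.todense() if scipy.sparse.issparse(M) else M, dtype=float).T
    if dense.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix.mtx is {M.shape} (genes x cells) but found "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    return dense, cells, genes


def write_matrix(es: ExpressionSet, path, fmt: str) -> None:
    """Write a set back out; the inverse of :func:`load_matrix`."""
    path = Path(path)
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.csr_matrix(es.matrix.T))
        pd.Series(es.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(es.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        pd.DataFrame({0: es.cell_ids, 1: es.batch_labels}).to_csv(
            path / "batches.tsv", sep="\t", header=False, index=False)
    elif fmt in ("csv", "tsv"):
        pd.DataFrame(es.matrix, index=es.cell_ids, columns=es.gene_ids).to_csv(
            path, sep="," if fmt == "csv" else "\t")
    elif fmt == "h5":
        es.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def qc_filter(es: ExpressionSet, max_library_size: float = np.inf,
              max_mito_fraction: float = 0.2,
              mito_gene_prefix: str = "MT-") -> ExpressionSet:
    """Drop cells with too-large library size or mitochondrial fraction."""
    if es.units != RAW_COUNTS:
        raise ValueError("qc_filter expects raw counts")
    if not 0.0 <= max_mito_fraction <= 1.0:
        raise ValueError("max_mito_fraction must be in [0, 1]")
    totals = es.matrix.sum(axis=1)
    mito = np.array([str(g).startswith(mito_gene_prefix) for g in es.gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, es.matrix[:, mito].sum(axis=1) / np.maximum(totals, 1e-300), 0.0)
    keep = (totals > 0) & (totals <= max_library_size) & (mito_frac <= max_mito_fraction)
    if not keep.any():
        culprit = ("max_library_size" if (mito_frac <= max_mito_fraction).any()
                   else "max_mito_fraction")
        raise ValueError(f"qc_filter removed every cell; threshold {culprit} is too strict")
    return es.subset_cells(np.flatnonzero(keep))


def log_tpm_transform(es: ExpressionSet, scale: float = 1e5) -> ExpressionSet:
    """Rescale each cell to sum to ``scale``, then log(1 + value)."""
    if es.units != RAW_COUNTS:
        raise ValueError("log_tpm_transform expects raw counts")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = es.matrix.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cells with zero total count present; run qc_filter "
                         "(or drop empty cells) before log_tpm_transform")
    out = np.log1p(es.matrix / totals[:, None] * scale)
    new = replace(es, matrix=out, units=LOG_TPM, metadata=dict(es.metadata))
    new.metadata["tpm_scale"] = scale
    return new


def shared_genes(sets: Sequence[ExpressionSet]) -> list:
    """Genes detected (non-zero in >= 1 cell) in every batch.

    Order follows the first set's gene order.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    expressed = []
    for s in sets:
        mask = (s.matrix != 0).any(axis=0)
        expressed.append({g for g, m in zip(s.gene_ids, mask) if m})
    common = set.intersection(*expressed)
    if not common:
        raise ValueError("no gene is detected in every batch")
    return [g for g in sets[0].gene_ids if g in common]


def select_hvg_union(sets: Sequence[ExpressionSet], n_top_per_batch: int,
                     combine: str = "union", n_bins: int = 20) -> list:
    """Per-batch highly variable genes, combined across batches.

    Genes are ranked within each batch by binned normalized dispersion
    (scanpy ``flavor="seurat"`` on log-scale values, ``n_bins`` mean
    bins) and exactly the top ``n_top_per_batch`` per batch are kept
    (ties broken by gene order); the per-batch lists are combined by
    ``union`` (default) or ``intersection``. The result keeps the first
    set's gene order.
    """
    import scanpy as sc

    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    genes0 = list(sets[0].gene_ids)
    for s in sets[1:]:
        if list(s.gene_ids) != genes0:
            raise ValueError("sets must be restricted to the shared gene list first")
    n_top = n_top_per_batch
    if n_top > len(genes0):
        warnings.warn(
            f"n_top_per_batch={n_top_per_batch} exceeds the {len(genes0)} shared genes; clipping")
        n_top = len(genes0)
    if n_top < 1:
        raise ValueError("n_top_per_batch must be >= 1")

    per_batch = []
    for s in sets:
        if s.units != LOG_TPM:
            raise ValueError("select_hvg_union expects log-TPM-like values")
        ad = s.to_anndata()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(ad, n_top_genes=n_top, flavor="seurat",
                                        n_bins=n_bins)
        disp = ad.var["dispersions_norm"].to_numpy(dtype=float)
        disp = np.where(np.isfinite(disp), disp, -np.inf)
        top = np.argsort(-disp, kind="stable")[:n_top]
        per_batch.append({s.gene_ids[i] for i in top})
    combined = set.union(*per_batch) if combine == "union" else set.intersection(*per_batch)
    return [g for g in genes0 if g in combined]


@dataclass(frozen=True)
class GenePartition:
    """A seeded random partition of a gene list into near-equal chunks."""

    chunks: tuple
    seed: int

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    def all_genes(self) -> list:
        return [g for c in self.chunks for g in c]


def chunk_genes(genes: Sequence, n_chunks: int, seed: int) -> GenePartition:
    """Randomly permute genes and split into near-equal disjoint chunks."""
    genes = list(genes)
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if n_chunks > len(genes):
        raise ValueError(f"cannot split {len(genes)} genes into {n_chunks} chunks")
    rng = np.random.default_rng(seed)
    perm = [genes[i] for i in rng.permutation(len(genes))]
    chunks = tuple(tuple(c) for c in np.array_split(np.array(perm, dtype=object), n_chunks))
    return GenePartition(chunks=chunks, seed=seed)


def preprocess_batches(sets: Sequence[ExpressionSet], n_top_per_batch: int = 2000,
                       max_library_size: float = np.inf, max_mito_fraction: float = 1.0,
                       mito_gene_prefix: str = "MT-", tpm_scale: float = 1e5,
                       hvg_combine: str = "union"):
    """QC -> log-TPM -> shared genes -> per-batch HVG, for a list of batches.

    Returns ``(hvg_sets, full_sets, hvg_genes)`` where ``full_sets`` are
    shared-gene log-TPM sets (whole-transcriptome mode) and ``hvg_sets``
    their restriction to the HVG list.
    """
    filtered = [qc_filter(s, max_library_size, max_mito_fraction, mito_gene_prefix) for s in sets]
    logged = [log_tpm_transform(s, tpm_scale) for s in filtered]
    common = shared_genes(logged)
    full = [s.subset_genes(common) for s in logged]
    hvgs = select_hvg_union(full, n_top_per_batch, combine=hvg_combine)
    return [s.subset_genes(hvgs) for s in full], full, hvgs
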