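"""In-memory container for a labelled cells x genes expression matrix."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG_TPM = "log_tpm"


@dataclass
class ExpressionSet:
    """A cells x genes matrix with batch (and optional cell-type) labels.

    ``units`` records the expression scale: ``"raw_counts"`` straight from a
    loader, ``"log_tpm"`` after :func:`scstyle.io_prep.log_tpm_transform`.
    All entries must be finite and non-negative; every batch label must
    annotate at least one cell.
    """

    matrix: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    batch_labels: np.ndarray
    celltype_labels: Optional[np.ndarray] = None
    units: str = RAW_COUNTS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        if self.celltype_labels is not None:
            self.celltype_labels = np.asarray(self.celltype_labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        n, d = self.matrix.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {d} matrix columns")
        if len(self.batch_labels) != n:
            raise ValueError(f"{len(self.batch_labels)} batch labels for {n} cells")
        if self.celltype_labels is not None and len(self.celltype_labels) != n:
            raise ValueError(f"{len(self.celltype_labels)} cell-type labels for {n} cells")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains NaN or Inf")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("matrix contains negative values")

    # -- basic views ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def batch_names(self) -> list:
        """Distinct batch labels in first-appearance order."""
        return list(pd.unique(self.batch_labels))

    def batch_mask(self, batch) -> np.ndarray:
        return self.batch_labels == batch

    def split_batches(self) -> dict:
        return {b: self.subset_cells(np.flatnonzero(self.batch_mask(b))) for b in self.batch_names}

    # -- subsetting -----------------------------------------------------
    def subset_cells(self, idx) -> "ExpressionSet":
        idx = np.asarray(idx)
        return replace(
            self,
            matrix=self.matrix[idx],
            cell_ids=self.cell_ids[idx],
            batch_labels=self.batch_labels[idx],
            celltype_labels=None if self.celltype_labels is None else self.celltype_labels[idx],
            metadata=dict(self.metadata),
        )

    def subset_genes(self, genes: Sequence) -> "ExpressionSet":
        """Restrict to the given gene ids, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from set: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        idx = np.array([pos[g] for g in genes], dtype=int)
        return replace(
            self,
            matrix=self.matrix[:, idx],
            gene_ids=self.gene_ids[idx],
            metadata=dict(self.metadata),
        )

    def copy(self) -> "ExpressionSet":
        return replace(
            self,
            matrix=self.matrix.copy(),
            metadata=dict(self.metadata),
        )

    # -- interop --------------------------------------------------------
    def to_anndata(self):
        import anndata

        obs = pd.DataFrame({"batch": pd.Categorical(self.batch_labels)},
                           index=self.cell_ids.astype(str))
        if self.celltype_labels is not None:
            obs["celltype"] = pd.Categorical(self.celltype_labels)
        ad = anndata.AnnData(
            X=self.matrix.copy(),
            obs=obs,
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )
        ad.uns["units"] = self.units
        return ad

    @classmethod
    def from_anndata(cls, adata, batch_key: str = "batch",
                     celltype_key: Optional[str] = "celltype",
                     units: Optional[str] = None) -> "ExpressionSet":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        if batch_key not in adata.obs:
            raise KeyError(f"batch key {batch_key!r} not in adata.obs")
        ct = None
        if celltype_key is not None and celltype_key in adata.obs:
            ct = adata.obs[celltype_key].to_numpy()
        return cls(
            matrix=np.asarray(X, dtype=float),
            cell_ids=adata.obs_names.to_numpy(),
            gene_ids=adata.var_names.to_numpy(),
            batch_labels=adata.obs[batch_key].to_numpy(),
            celltype_labels=ct,
            units=units or adata.uns.get("units", RAW_COUNTS),
        )


def concat_sets(sets: Sequence[ExpressionSet]) -> ExpressionSet:
    """Stack cell rows of sets sharing an identical gene axis."""
    if not sets:
        raise ValueError("no sets to concatenate")
    genes = sets[0].gene_ids
    for s in sets[1:]:
        if not np.array_equal(s.gene_ids, genes):
            raise ValueError("sets must share an identical gene axis; restrict to shared genes first")
    units = {s.units for s in sets}
    if len(units) > 1:
        raise ValueError(f"sets mix units: {units}")
    has_ct = all(s.celltype_labels is not None for s in sets)
    return ExpressionSet(
        matrix=np.vstack([s.matrix for s in sets]),
        cell_ids=np.concatenate([s.cell_ids for s in sets]),
        gene_ids=genes,
        batch_labels=np.concatenate([s.batch_labels for s in sets]),
        celltype_labels=np.concatenate([s.celltype_labels for s in sets]) if has_ct else None,
        units=sets[0].units,
    )
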