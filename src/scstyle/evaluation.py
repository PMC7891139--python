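"""Single-cell-level evaluation of batch mixing.

Two successive local classifiers label every cell:

* **positive** — at least 50% of the cell's k nearest neighbours share
  its cell type, with k = min(k_cap, type size) and the query cell
  excluded; otherwise negative. This measures preservation of biological
  structure.
* **true positive** — a positive cell whose neighbourhood batch
  composition is consistent with its type's *global* batch composition
  under a three-sigma binomial rule: with p_i = N_i / sum_j N_j the
  fraction of the type's cells in batch i, the neighbourhood count k_i
  must fall inside [max(0, k p_i - 3 sqrt(k p_i (1-p_i))),
  k p_i + 3 sqrt(k p_i (1-p_i))] for every batch i. This measures
  batch mixing without penalizing genuinely batch-specific types (their
  interval is degenerate).

The rule is space-agnostic: any per-cell coordinate matrix may be
evaluated (corrected expression, a PCA, an external 2-D embedding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

NEGATIVE = "negative"
FALSE_POSITIVE = "false_positive"
TRUE_POSITIVE = "true_positive"


@dataclass
class MixtureReport:
    """Per-cell mixing labels plus summary proportions."""

    table: pd.DataFrame                # cell, label, k_used, one count column per batch
    batch_names: list
    n_excluded_singletons: int = 0
    embedding_note: str = ""

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def proportion_positive(self) -> float:
        lab = self.labels
        n = len(lab)
        return float(np.isin(lab, [FALSE_POSITIVE, TRUE_POSITIVE]).sum() / n) if n else 0.0

    @property
    def proportion_true_positive(self) -> float:
        lab = self.labels
        return float((lab == TRUE_POSITIVE).sum() / len(lab)) if len(lab) else 0.0

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _knn_table(embedding: np.ndarray, k_used: np.ndarray) -> list:
    """Stable-tie-broken nearest-neighbour lists, self excluded."""
    D = cdist(embedding, embedding)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return [order[i, :k_used[i]] for i in range(len(order))]


def classify_positive(embedding: np.ndarray, celltypes: np.ndarray,
                      k_cap: int = 100, exact: bool = True):
    """Positive/negative labels plus the per-cell k actually used.

    Returns ``(positive, k_used, neighbour_lists)``; singleton cell types
    are marked negative with a warning.
    """
    embedding = np.asarray(embedding, dtype=float)
    celltypes = np.asarray(celltypes)
    if embedding.shape[0] != len(celltypes):
        raise ValueError("embedding rows and cell-type labels differ in length")
    uniq, counts = np.unique(celltypes, return_counts=True)
    size = dict(zip(uniq, counts))
    singles = [t for t in uniq if size[t] < 2]
    if singles:
        warnings.warn(f"cell types with a single cell marked negative: {singles}")
    k_used = np.array([min(k_cap, size[t]) for t in celltypes], dtype=int)
    nbrs = _knn_table(embedding, k_used)
    positive = np.zeros(len(celltypes), dtype=bool)
    for i, nb in enumerate(nbrs):
        if size[celltypes[i]] < 2:
            continue
        same = (celltypes[nb] == celltypes[i]).sum()
        positive[i] = same >= 0.5 * k_used[i]
    return positive, k_used, nbrs


def classify_true_positive(positive: np.ndarray, embedding: np.ndarray,
                           celltypes: np.ndarray, batches: np.ndarray,
                           k_used: np.ndarray | None = None,
                           nbrs: list | None = None,
                           k_cap: int = 100,
                           cell_ids: np.ndarray | None = None,
                           embedding_note: str = "") -> MixtureReport:
    """Three-sigma batch-composition test on the positive cells."""
    embedding = np.asarray(embedding, dtype=float)
    celltypes = np.asarray(celltypes)
    batches = np.asarray(batches)
    if nbrs is None or k_used is None:
        uniq, counts = np.unique(celltypes, return_counts=True)
        size = dict(zip(uniq, counts))
        k_used = np.array([min(k_cap, size[t]) for t in celltypes], dtype=int)
        nbrs = _knn_table(embedding, k_used)

    batch_names = list(pd.unique(batches))
    n_cells = len(celltypes)
    uniq_types, tcounts = np.unique(celltypes, return_counts=True)
    tsize = dict(zip(uniq_types, tcounts))
    # global batch composition per type
    p_table = {}
    for t in uniq_types:
        mask = celltypes == t
        Ni = np.array([(batches[mask] == b).sum() for b in batch_names], dtype=float)
        p_table[t] = Ni / Ni.sum()

    labels = np.full(n_cells, NEGATIVE, dtype=object)
    comp = np.zeros((n_cells, len(batch_names)), dtype=int)
    for i in range(n_cells):
        nb = nbrs[i]
        ki = np.array([(batches[nb] == b).sum() for b in batch_names])
        comp[i] = ki
        if not positive[i]:
            continue
        k = k_used[i]
        p = p_table[celltypes[i]]
        sigma = np.sqrt(k * p * (1.0 - p))
        lo = np.maximum(0.0, k * p - 3.0 * sigma)
        hi = k * p + 3.0 * sigma
        ok = np.all((ki >= lo) & (ki <= hi))
        labels[i] = TRUE_POSITIVE if ok else FALSE_POSITIVE

    evaluated = np.array([tsize[t] >= 2 for t in celltypes])
    table = pd.DataFrame({
        "cell": cell_ids if cell_ids is not None else np.arange(n_cells),
        "celltype": celltypes,
        "batch": batches,
        "label": labels,
        "k_used": k_used,
    })
    for j, b in enumerate(batch_names):
        table[f"knn_{b}"] = comp[:, j]
    report = MixtureReport(
        table=table[evaluated].reset_index(drop=True),
        batch_names=batch_names,
        n_excluded_singletons=int((~evaluated).sum()),
        embedding_note=embedding_note,
    )
    return report


def summarize(report: MixtureReport) -> tuple[float, float]:
    """(proportion_positive, proportion_true_positive) over evaluated cells."""
    return report.proportion_positive, report.proportion_true_positive


def evaluate_mixing(embedding: np.ndarray, celltypes: np.ndarray,
                    batches: np.ndarray, k_cap: int = 100,
                    cell_ids: np.ndarray | None = None,
                    embedding_note: str = "") -> MixtureReport:
    """Run both classifiers on one embedding."""
    positive, k_used, nbrs = classify_positive(embedding, celltypes, k_cap=k_cap)
    return classify_true_positive(positive, embedding, celltypes, batches,
                                  k_used=k_used, nbrs=nbrs, cell_ids=cell_ids,
                                  embedding_note=embedding_note)
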