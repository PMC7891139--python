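"""Mutual-nearest-neighbour pairs and their random-walk expansion.

Cross-batch cell pairs seed the adversarial correction: an MNN pair is
two cells, one per batch, each inside the other's k nearest across-batch
neighbours (computed in content-code space). Because raw MNN pairs tend
to cover only the densest part of the shared cell types, each seed pair
is extended by m chained within-batch random-walk steps over k1-nearest
neighbour graphs; the resulting walk pairs ("rwMNN" pairs) sketch the
full distribution of the shared types. Pairing runs on a subsample of at
most s cells per batch; full batches are only ever transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class PairParams:
    """Hyperparameters s, k1, k, m of the pairing stage.

    Defaults follow the s=3000 subsample cap with k1 = s_eff/100 and
    k = k1/2 (floored, at least 1), walk length m = 50. ``k1`` and ``k``
    may be pinned explicitly; otherwise they are derived from the
    effective subsample size via :meth:`resolve`.
    """

    s: int = 3000
    k1: int | None = None
    k: int | None = None
    m: int = 50

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.m < 0:
            raise ValueError("walk length m must be >= 0")
        if self.k1 is not None and self.k1 < 1:
            raise ValueError("k1 must be >= 1")
        if self.k is not None and (self.k < 1 or (self.k1 is not None and self.k > self.k1)):
            raise ValueError("k must satisfy 1 <= k <= k1")

    def resolve(self, *batch_sizes: int) -> tuple[int, int]:
        """(k1, k) for the smallest effective subsample among the batches."""
        s_eff = min([self.s, *batch_sizes])
        k1 = self.k1 if self.k1 is not None else max(1, s_eff // 100)
        k = self.k if self.k is not None else max(1, k1 // 2)
        return k1, min(k, k1)


@dataclass
class PairSet:
    """Ordered cross-batch pairs: seeds (walk_step 0) plus walk extensions."""

    pairs: np.ndarray                  # (N, 2) int: [index_a, index_b]
    origin: np.ndarray                 # (N,) str: "seed" | "walk"
    walk_step: np.ndarray              # (N,) int, 0 for seeds
    batch_a_id: object = None
    batch_b_id: object = None

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.origin = np.asarray(self.origin, dtype=object)
        self.walk_step = np.asarray(self.walk_step, dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def m_seeds(self) -> int:
        return int((self.origin == "seed").sum())

    @property
    def index_a(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def index_b(self) -> np.ndarray:
        return self.pairs[:, 1]

    def seeds(self) -> "PairSet":
        m = self.origin == "seed"
        return PairSet(self.pairs[m], self.origin[m], self.walk_step[m],
                       self.batch_a_id, self.batch_b_id)

    def deduplicated(self) -> "PairSet":
        """Drop repeated (a, b) pairs, keeping the first occurrence."""
        _, first = np.unique(self.pairs, axis=0, return_index=True)
        keep = np.sort(first)
        return PairSet(self.pairs[keep], self.origin[keep], self.walk_step[keep],
                       self.batch_a_id, self.batch_b_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "batch_a_cell": self.pairs[:, 0],
            "batch_b_cell": self.pairs[:, 1],
            "origin": self.origin,
            "walk_step": self.walk_step,
        })

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# neighbour search backends
# ---------------------------------------------------------------------------

def _topk_stable(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest entries per row; ties broken by index."""
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def subsample_cells(n_cells: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """All indices (in order) if n_cells <= s, else s drawn without replacement."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_cells <= s:
        return np.arange(n_cells)
    return rng.choice(n_cells, size=s, replace=False)


def knn_within(codes: np.ndarray, k1: int, exact: bool = True,
               seed: int = 0) -> np.ndarray:
    """(n, k1) table of each cell's k1 nearest other cells (self excluded).

    ``exact=True`` is an exhaustive Euclidean search with stable
    index-order tie-breaking (the test ground truth); ``exact=False``
    uses a pynndescent approximate index.
    """
    codes = np.asarray(codes, dtype=float)
    n = codes.shape[0]
    if k1 >= n:
        raise ValueError(f"k1={k1} must be < number of cells ({n})")
    if exact:
        D = cdist(codes, codes)
        np.fill_diagonal(D, np.inf)
        return _topk_stable(D, k1)
    return _approx_knn_within(codes, k1, seed)


def _approx_knn_within(codes: np.ndarray, k1: int, seed: int) -> np.ndarray:
    try:
        from pynndescent import NNDescent
    except ImportError as err:  # pragma: no cover
        raise ImportError("approximate neighbour search needs pynndescent; "
                          "use exact=True instead") from err
    index = NNDescent(codes, n_neighbors=min(k1 + 2, codes.shape[0]), random_state=seed)
    idx, _ = index.neighbor_graph
    out = np.empty((codes.shape[0], k1), dtype=int)
    for i in range(codes.shape[0]):
        row = idx[i][idx[i] != i]
        out[i] = row[:k1]
    return out


def cross_knn(query: np.ndarray, reference: np.ndarray, k: int,
              exact: bool = True, seed: int = 0) -> np.ndarray:
    """(n_query, k) nearest reference cells for each query cell."""
    query = np.asarray(query, float)
    reference = np.asarray(reference, float)
    if k > reference.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {reference.shape[0]}")
    if exact:
        return _topk_stable(cdist(query, reference), k)
    try:
        from pynndescent import NNDescent
    except ImportError as err:  # pragma: no cover
        raise ImportError("approximate neighbour search needs pynndescent; "
                          "use exact=True instead") from err
    index = NNDescent(reference, n_neighbors=min(max(k + 1, 10), reference.shape[0]),
                      random_state=seed)
    idx, _ = index.query(query, k=k)
    return idx


def mutual_nn_pairs(codes_a: np.ndarray, codes_b: np.ndarray, k: int,
                    exact: bool = True, seed: int = 0,
                    batch_a_id=None, batch_b_id=None) -> PairSet:
    """Seed pairs: (i, j) with j in kNN_B(i) and i in kNN_A(j).

    Output is ordered lexicographically by (i, j). An empty result is
    returned with a warning rather than raised.
    """
    codes_a = np.atleast_2d(np.asarray(codes_a, float))
    codes_b = np.atleast_2d(np.asarray(codes_b, float))
    if k >= min(codes_a.shape[0], codes_b.shape[0]) + 1:
        raise ValueError("k must be < min(batch sizes) + 1")
    ab = cross_knn(codes_a, codes_b, k, exact=exact, seed=seed)
    ba = cross_knn(codes_b, codes_a, k, exact=exact, seed=seed)
    in_ba = [set(row) for row in ba]
    found = [(i, j) for i in range(codes_a.shape[0]) for j in sorted(ab[i])
             if i in in_ba[j]]
    if not found:
        warnings.warn("no mutual nearest neighbour pairs found")
        pairs = np.empty((0, 2), dtype=int)
    else:
        pairs = np.array(sorted(found), dtype=int)
    n = len(pairs)
    return PairSet(pairs, np.array(["seed"] * n, object), np.zeros(n, int),
                   batch_a_id, batch_b_id)


def random_walk_extend(seeds: PairSet, knn_a: np.ndarray, knn_b: np.ndarray,
                       m: int, rng: np.random.Generator,
                       chain: bool = True, deduplicate: bool = False) -> PairSet:
    """Extend each seed pair by m chained within-batch walk steps.

    At every step one cell is drawn uniformly from the k1 within-batch
    neighbours of the current batch-A member and, independently, one from
    those of the current batch-B member; the new pair is recorded and
    (with ``chain=True``, the default) becomes the walk state for the
    next step. ``chain=False`` restarts every step from the original
    seed. Output length is m_seeds * (m + 1) before deduplication.
    """
    if m < 0:
        raise ValueError("walk length m must be >= 0")
    if len(seeds) == 0:
        raise ValueError("cannot extend an empty seed set")
    knn_a = np.asarray(knn_a, int)
    knn_b = np.asarray(knn_b, int)
    k1a, k1b = knn_a.shape[1], knn_b.shape[1]
    n_seeds = len(seeds)
    cur_a = seeds.index_a.copy()
    cur_b = seeds.index_b.copy()
    all_pairs = [seeds.pairs]
    steps = [np.zeros(n_seeds, int)]
    for step in range(1, m + 1):
        src_a = cur_a if chain else seeds.index_a
        src_b = cur_b if chain else seeds.index_b
        cur_a = knn_a[src_a, rng.integers(0, k1a, size=n_seeds)]
        cur_b = knn_b[src_b, rng.integers(0, k1b, size=n_seeds)]
        all_pairs.append(np.column_stack([cur_a, cur_b]))
        steps.append(np.full(n_seeds, step))
    pairs = np.vstack(all_pairs)
    walk_step = np.concatenate(steps)
    origin = np.where(walk_step == 0, "seed", "walk").astype(object)
    out = PairSet(pairs, origin, walk_step, seeds.batch_a_id, seeds.batch_b_id)
    return out.deduplicated() if deduplicate else out


def build_rwmnn_pairs(codes_a: np.ndarray, codes_b: np.ndarray,
                      params: PairParams, rng: np.random.Generator,
                      exact: bool = True, chain: bool = True,
                      deduplicate: bool = False,
                      batch_a_id=None, batch_b_id=None) -> tuple[PairSet, np.ndarray, np.ndarray]:
    """Subsample, find MNN seeds and walk-extend, in one call.

    Returns ``(pairset, sub_a, sub_b)`` where the pair indices refer to
    rows of the two subsample index arrays.
    """
    na, nb = codes_a.shape[0], codes_b.shape[0]
    sub_a = subsample_cells(na, params.s, rng)
    sub_b = subsample_cells(nb, params.s, rng)
    ca, cb = codes_a[sub_a], codes_b[sub_b]
    k1, k = params.resolve(len(sub_a), len(sub_b))
    seed_int = int(rng.integers(0, 2**31 - 1))
    seeds = mutual_nn_pairs(ca, cb, k, exact=exact, seed=seed_int,
                            batch_a_id=batch_a_id, batch_b_id=batch_b_id)
    if len(seeds) == 0:
        return seeds, sub_a, sub_b
    if params.m == 0:
        return seeds, sub_a, sub_b
    knn_a = knn_within(ca, min(k1, len(sub_a) - 1), exact=exact, seed=seed_int)
    knn_b = knn_within(cb, min(k1, len(sub_b) - 1), exact=exact, seed=seed_int)
    extended = random_walk_extend(seeds, knn_a, knn_b, params.m, rng,
                                  chain=chain, deduplicate=deduplicate)
    return extended, sub_a, sub_b
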