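"""Seeded multi-batch scRNA-seq count simulator with known ground truth.

The generator emulates the structure the correction framework is designed
for: several batches measuring overlapping sets of cell types, where some
types are deliberately batch-specific (a correct integration must keep
them separate while mixing the shared types). Counts are negative
binomial (gamma-Poisson) around per-type mean profiles; batch effects are
gene-wise additive shifts on the log-scale mean plus gene-wise
multiplicative factors, with optional extra dropout. A handful of genes
per batch receive large planted shifts (batch-diagnostic genes) and each
type carries planted marker genes, so probe-classifier importance scores
can be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .data import ExpressionSet


@dataclass
class BatchEffectSpec:
    """Gene-wise distortion applied by one batch.

    ``shift_sigma`` draws the additive log-scale shift vector; ``n_diag``
    genes additionally receive a planted shift of ``diag_shift`` magnitude
    (alternating sign) and are reported as ground truth. ``mult_sigma``
    draws the lognormal multiplicative factor vector. ``dropout`` is the
    probability that an observed count is zeroed (extra, batch-driven).
    """

    shift_sigma: float = 0.0
    n_diag: int = 0
    diag_shift: float = 3.5
    mult_sigma: float = 0.0
    dropout: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability")


@dataclass
class SimulationDesign:
    """Full specification of a simulated multi-batch dataset.

    ``cell_counts`` maps cell type -> per-batch cell counts (length
    ``n_batches``); a zero marks the type as absent from that batch. Type
    mean profiles are lognormal: a shared gene baseline (log-mean
    ``base_log_mean``, sigma ``base_log_sigma``) modulated per type by a
    lognormal jitter (sigma ``type_jitter_sigma``) and boosted
    ``marker_fold``-fold on ``n_markers_per_type`` planted marker genes.
    Counts are NB with dispersion ``nb_dispersion`` (var = m + phi m^2).
    """

    n_batches: int
    n_genes: int
    cell_counts: dict
    batch_effects: list = field(default_factory=list)
    base_log_mean: float = 1.0
    base_log_sigma: float = 1.0
    type_jitter_sigma: float = 0.6
    n_markers_per_type: int = 5
    marker_fold: float = 4.0
    nb_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not self.batch_effects:
            self.batch_effects = [BatchEffectSpec() for _ in range(self.n_batches)]
        if len(self.batch_effects) != self.n_batches:
            raise ValueError("one BatchEffectSpec per batch required")
        counts = np.array([self.cell_counts[t] for t in self.cell_counts])
        if counts.shape[1] != self.n_batches:
            raise ValueError("cell_counts rows must have n_batches entries")
        if (counts < 0).any():
            raise ValueError("cell counts must be non-negative")
        shared = ((counts > 0).sum(axis=1) >= 2).any()
        if not shared:
            raise ValueError("at least one cell type must be present in >= 2 batches")

    @property
    def types(self) -> list:
        return list(self.cell_counts)

    @property
    def batch_names(self) -> list:
        return [f"batch{i}" for i in range(self.n_batches)]

    def presence_mask(self) -> pd.DataFrame:
        return pd.DataFrame(
            {b: [self.cell_counts[t][i] > 0 for t in self.types]
             for i, b in enumerate(self.batch_names)},
            index=self.types,
        )


@dataclass
class GroundTruth:
    """Everything the generator knows, for exact downstream validation."""

    type_means: pd.DataFrame           # genes x types, pre-distortion means
    markers: dict                      # type -> list of marker gene ids
    batch_shift: pd.DataFrame          # genes x batches additive log shifts
    batch_mult: pd.DataFrame           # genes x batches multiplicative factors
    diag_genes: dict                   # batch -> list of planted diagnostic gene ids
    dropout: dict                      # batch -> extra dropout probability


def simulate(design: SimulationDesign) -> tuple[ExpressionSet, GroundTruth]:
    """Draw a counts matrix plus ground-truth tables from a design."""
    rng = np.random.default_rng(design.seed)
    G = design.n_genes
    gene_ids = np.array([f"g{i:04d}" for i in range(G)], dtype=object)
    types = design.types

    base = rng.lognormal(design.base_log_mean, design.base_log_sigma, size=G)
    # plant only on well-expressed genes: a fold change or log-shift on a
    # near-zero gene would be invisible after normalization
    eligible = np.flatnonzero(base >= np.median(base))
    perm = eligible[rng.permutation(len(eligible))]
    markers = {}
    for i, t in enumerate(types):
        lo = i * design.n_markers_per_type
        markers[t] = list(gene_ids[perm[lo:lo + design.n_markers_per_type]])
    n_used = len(types) * design.n_markers_per_type
    diag_pool = perm[n_used:]          # well-expressed, non-marker genes
    # marker genes are planted as true markers: jitter-free, boosted
    # marker_fold-times in their own type and suppressed by the same
    # factor elsewhere, so their type contrast exceeds by construction
    # what the lognormal jitter can produce by chance
    marker_cols = {t: np.array([np.flatnonzero(gene_ids == g)[0] for g in ms])
                   for t, ms in markers.items()}
    mu = {}
    for t in types:
        m = base * rng.lognormal(0.0, design.type_jitter_sigma, size=G)
        for u in types:
            cols = marker_cols[u]
            m[cols] = base[cols] * (design.marker_fold if u == t
                                    else 1.0 / design.marker_fold)
        mu[t] = m

    shifts, mults, diag, dropout = {}, {}, {}, {}
    for bi, (bname, eff) in enumerate(zip(design.batch_names, design.batch_effects)):
        shift = rng.normal(0.0, eff.shift_sigma, size=G) if eff.shift_sigma > 0 else np.zeros(G)
        # diagnostic genes are planted as unambiguous batch markers: their
        # shift replaces (never stacks on) the background draw and their
        # multiplicative factor carries no extra noise
        dsel = (rng.choice(diag_pool, size=eff.n_diag, replace=False)
                if eff.n_diag else np.array([], int))
        signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(eff.n_diag)])
        shift[dsel] = eff.diag_shift * signs
        mult = rng.lognormal(0.0, eff.mult_sigma, size=G) if eff.mult_sigma > 0 else np.ones(G)
        mult[dsel] = 1.0
        shifts[bname], mults[bname] = shift, mult
        diag[bname] = list(gene_ids[dsel])
        dropout[bname] = eff.dropout

    phi = design.nb_dispersion
    blocks, batch_lab, type_lab = [], [], []
    for bi, bname in enumerate(design.batch_names):
        eff = design.batch_effects[bi]
        for t in types:
            n = design.cell_counts[t][bi]
            if n == 0:
                continue
            mean = mu[t] * mults[bname] * np.exp(shifts[bname])
            lam = rng.gamma(1.0 / phi, mean * phi, size=(n, G)) if phi > 0 else np.tile(mean, (n, 1))
            counts = rng.poisson(lam).astype(float)
            if eff.dropout > 0:
                counts *= rng.random((n, G)) >= eff.dropout
            blocks.append(counts)
            batch_lab += [bname] * n
            type_lab += [t] * n

    X = np.vstack(blocks)
    cell_ids = np.array([f"c{i:05d}" for i in range(X.shape[0])], dtype=object)
    es = ExpressionSet(X, cell_ids, gene_ids, np.array(batch_lab, object),
                       np.array(type_lab, object))
    truth = GroundTruth(
        type_means=pd.DataFrame({t: mu[t] for t in types}, index=gene_ids),
        markers=markers,
        batch_shift=pd.DataFrame(shifts, index=gene_ids),
        batch_mult=pd.DataFrame(mults, index=gene_ids),
        diag_genes=diag,
        dropout=dropout,
    )
    return es, truth


def default_benchmark_design(scale: str, seed: int = 0) -> SimulationDesign:
    """Named benchmark designs: ``tiny``, ``small`` or ``medium``.

    ``small`` mirrors the benchmark layout with deliberately batch-specific
    populations: two batches of 400 cells, two shared types and one type
    private to each batch, under an additive+multiplicative batch effect
    with three planted batch-diagnostic genes.
    """
    if scale == "tiny":
        return SimulationDesign(
            n_batches=2, n_genes=60,
            cell_counts={"A": [30, 30], "B": [30, 30], "C": [20, 20]},
            batch_effects=[BatchEffectSpec(),
                           BatchEffectSpec(shift_sigma=0.8, n_diag=2, mult_sigma=0.3)],
            n_markers_per_type=3,
            seed=seed,
        )
    if scale == "small":
        return SimulationDesign(
            n_batches=2, n_genes=200,
            cell_counts={"A": [150, 150], "B": [150, 150], "C": [100, 0], "D": [0, 100]},
            batch_effects=[BatchEffectSpec(),
                           BatchEffectSpec(shift_sigma=0.8, n_diag=3, diag_shift=3.5,
                                           mult_sigma=0.3)],
            seed=seed,
        )
    if scale == "medium":
        return SimulationDesign(
            n_batches=3, n_genes=2000,
            cell_counts={
                "A": [250, 250, 250], "B": [250, 250, 250], "C": [200, 200, 0],
                "D": [150, 0, 150], "E": [150, 150, 150], "F": [0, 150, 200],
            },
            batch_effects=[
                BatchEffectSpec(),
                BatchEffectSpec(shift_sigma=0.8, n_diag=5, mult_sigma=0.3, dropout=0.05),
                BatchEffectSpec(shift_sigma=1.0, n_diag=5, mult_sigma=0.4, dropout=0.10),
            ],
            seed=seed,
        )
    raise ValueError(f"unknown scale {scale!r}; expected tiny, small or medium")
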