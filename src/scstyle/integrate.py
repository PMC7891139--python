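"""End-to-end multi-batch integration.

The anchor batch — by default the one with the largest total gene-wise
variance — is never modified; every other batch, in decreasing order of
total variance, is paired against the current anchor pool in content-code
space, corrected by a freshly trained adversarial generator, and appended
to the pool. Stage I is trained once, jointly, on all batches (its batch
indicator has one slot per batch); only stage II is incremental.

Determinism: one global seed fans out to per-component seeds through
``numpy.random.SeedSequence`` keyed by *role* (stage I, pairing round,
GAN round), and batches are canonicalized by batch id before training, so
results do not depend on the order in which batches are supplied.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionSet, concat_sets
from .io_prep import chunk_genes
from .pairs import PairParams, PairSet, build_rwmnn_pairs
from .stage1 import Stage1Config, Stage1Model, build_stage1, encode, train_stage1
from .stage2 import GanConfig, build_gan, train_stage2, transform

logger = logging.getLogger(__name__)


@dataclass
class IntegrationConfig:
    stage1: Stage1Config = field(default_factory=Stage1Config)
    gan: GanConfig = field(default_factory=GanConfig)
    pair: PairParams = field(default_factory=PairParams)
    exact_nn: bool | None = None       # None: exact up to 2048 pooled cells
    walk_chain: bool = True
    deduplicate_pairs: bool = False

    def use_exact(self, n_cells: int) -> bool:
        if self.exact_nn is not None:
            return self.exact_nn
        return n_cells <= 2048


@dataclass
class IntegrationPlan:
    """Anchor choice and correction order, by decreasing total variance."""

    anchor_batch_id: object
    order: list
    variances: dict
    user_override: bool = False


@dataclass
class IntegrationResult:
    corrected: ExpressionSet
    provenance: pd.DataFrame           # cell_id, original_batch, round, corrected
    plan: IntegrationPlan
    stage1_model: Stage1Model
    stage1_report: pd.DataFrame
    codes: np.ndarray                  # stage-I codes, aligned with `corrected` rows
    round_info: list                   # per round: dict with pair counts and logs


def total_variance(es: ExpressionSet) -> float:
    """Sum of per-gene variances (the space the model trains in)."""
    return float(np.var(es.matrix, axis=0).sum())


def plan_integration(sets: list, override_anchor=None,
                     override_order=None) -> IntegrationPlan:
    """Anchor = argmax total variance; remainder sorted descending.

    Ties break lexicographically by batch id; explicit overrides are
    honoured verbatim.
    """
    if len(sets) < 2:
        raise ValueError("integration needs at least two batches")
    ids = [s.batch_names[0] if len(s.batch_names) == 1 else None for s in sets]
    if any(i is None for i in ids):
        raise ValueError("each input set must contain exactly one batch")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate batch ids across input sets")
    var = {i: total_variance(s) for i, s in zip(ids, sets)}
    ranked = sorted(ids, key=lambda b: (-var[b], str(b)))
    user_override = override_anchor is not None or override_order is not None
    anchor = ranked[0] if override_anchor is None else override_anchor
    if anchor not in var:
        raise ValueError(f"override anchor {anchor!r} is not an input batch")
    rest = [b for b in ranked if b != anchor]
    if override_order is not None:
        unknown = [b for b in override_order if b not in var]
        if unknown:
            raise ValueError(f"override order names unknown batches: {unknown}")
        if set(override_order) != set(rest):
            raise ValueError("override order must list every non-anchor batch exactly once")
        rest = list(override_order)
    return IntegrationPlan(anchor_batch_id=anchor, order=rest, variances=var,
                           user_override=user_override)


def _canonical_sets(sets: list) -> list:
    return sorted(sets, key=lambda s: str(s.batch_names[0]))


def _round_seed(seed_root: np.random.SeedSequence, role: str, round_idx: int) -> int:
    # stable role-keyed derivation, independent of input order and process
    role_key = zlib.crc32(role.encode()) % (2**31)
    base = np.random.SeedSequence([seed_root.entropy, role_key, round_idx])
    return int(base.generate_state(1)[0] % (2**31))


def integrate_all(sets: list, config: IntegrationConfig | None = None,
                  seed: int = 0, plan: IntegrationPlan | None = None,
                  stage1_epochs: int | None = None,
                  stage2_epochs: int | None = None,
                  stage1_model: Stage1Model | None = None) -> IntegrationResult:
    """Run the full two-stage pipeline on preprocessed batches.

    ``sets`` must share one gene axis with log-TPM-like values (HVG
    restriction recommended). Anchor cells pass through bit-identical;
    all other cells are returned corrected, with provenance columns.
    Pass ``stage1_model`` to reuse an already-trained encoder (e.g. when
    re-running stage II under different pairing settings).
    """
    config = config or IntegrationConfig()
    sets = _canonical_sets(sets)
    joint = concat_sets(sets)
    n_batches = len(sets)
    d = joint.n_genes
    root = np.random.SeedSequence(seed)

    if stage1_model is None:
        s1_seed = _round_seed(root, "stage1", 0)
        model0 = build_stage1(d, n_batches, seed=s1_seed, config=config.stage1)
        model, s1_report = train_stage1(model0, joint, epochs=stage1_epochs,
                                        seed=s1_seed)
    else:
        model, s1_report = stage1_model, pd.DataFrame()
    codes = encode(model, joint.matrix)

    plan = plan or plan_integration(sets)
    by_id = {s.batch_names[0]: s for s in sets}
    joint_idx = {}
    offset = 0
    for s in sets:
        joint_idx[s.batch_names[0]] = np.arange(offset, offset + s.n_cells)
        offset += s.n_cells

    pool_idx = joint_idx[plan.anchor_batch_id].copy()
    corrected_rows = {i: joint.matrix[i] for i in pool_idx}
    round_of = {i: 0 for i in pool_idx}
    flag_corrected = {i: False for i in pool_idx}
    round_info = []

    for rnd, batch_id in enumerate(plan.order, start=1):
        src_idx = joint_idx[batch_id]
        pool_X = np.vstack([corrected_rows[i] for i in pool_idx])
        src_set = by_id[batch_id]
        rng = np.random.default_rng(_round_seed(root, "pairs", rnd))
        exact = config.use_exact(max(len(pool_idx), len(src_idx)))
        pairset, sub_src, sub_pool = build_rwmnn_pairs(
            codes[src_idx], codes[pool_idx], config.pair, rng, exact=exact,
            chain=config.walk_chain, deduplicate=config.deduplicate_pairs,
            batch_a_id=batch_id, batch_b_id="anchor_pool",
        )
        info = {"batch": batch_id, "round": rnd, "n_seed_pairs": pairset.m_seeds,
                "n_pairs": len(pairset), "exact_nn": exact}
        if len(pairset) == 0:
            warnings.warn(f"batch {batch_id!r}: no mutual pairs against the anchor pool; "
                          "appended uncorrected")
            info["fallback_uncorrected"] = True
            X_corr = src_set.matrix
            gan = None
        else:
            info["fallback_uncorrected"] = False
            gan_seed = _round_seed(root, "gan", rnd)
            gan0 = build_gan(d, seed=gan_seed, config=config.gan)
            gan, log = train_stage2(
                gan0, pairset,
                X_source=src_set.matrix[sub_src],
                X_anchor=pool_X[sub_pool],
                epochs=stage2_epochs, seed=gan_seed,
            )
            info["train_log"] = log
            X_corr = transform(gan, src_set.matrix)
        for row, i in enumerate(src_idx):
            corrected_rows[i] = X_corr[row]
            round_of[i] = rnd
            flag_corrected[i] = not info["fallback_uncorrected"]
        pool_idx = np.concatenate([pool_idx, src_idx])
        round_info.append(info)
        logger.info("round %d: batch %s, %d seed pairs, %d pairs",
                    rnd, batch_id, info["n_seed_pairs"], info["n_pairs"])

    out_idx = np.concatenate([joint_idx[plan.anchor_batch_id]]
                             + [joint_idx[b] for b in plan.order])
    matrix = np.vstack([corrected_rows[i] for i in out_idx])
    corrected = ExpressionSet(
        matrix=matrix,
        cell_ids=joint.cell_ids[out_idx],
        gene_ids=joint.gene_ids,
        batch_labels=joint.batch_labels[out_idx],
        celltype_labels=None if joint.celltype_labels is None else joint.celltype_labels[out_idx],
        units=joint.units,
    )
    provenance = pd.DataFrame({
        "cell_id": joint.cell_ids[out_idx],
        "original_batch": joint.batch_labels[out_idx],
        "round": [round_of[i] for i in out_idx],
        "corrected": [flag_corrected[i] for i in out_idx],
    })
    return IntegrationResult(corrected=corrected, provenance=provenance, plan=plan,
                             stage1_model=model, stage1_report=s1_report,
                             codes=codes[out_idx], round_info=round_info)


def correct_full_transcriptome(sets: list, codes: np.ndarray,
                               plan: IntegrationPlan, n_chunks: int = 10,
                               config: IntegrationConfig | None = None,
                               seed: int = 0,
                               stage2_epochs: int | None = None) -> IntegrationResult | ExpressionSet:
    """Whole-transcriptome correction by gene chunking.

    ``sets`` carry the full shared gene list; ``codes`` are stage-I codes
    (computed on the HVG space) aligned with the canonicalized,
    concatenated cell order. Genes are randomly partitioned into
    ``n_chunks`` near-equal chunks; rwMNN pairs are computed once per
    correction round and reused across chunks, with one independent
    corrector trained per chunk. Columns are reassembled in the original
    gene order.
    """
    config = config or IntegrationConfig()
    sets = _canonical_sets(sets)
    joint = concat_sets(sets)
    if codes.shape[0] != joint.n_cells:
        raise ValueError("codes must align with the concatenated cells")
    root = np.random.SeedSequence(seed)
    genes = list(joint.gene_ids)
    partition = chunk_genes(genes, n_chunks, seed=_round_seed(root, "chunks", 0))
    for c in partition.chunks:
        if len(c) < 2:
            raise ValueError("a gene chunk has < 2 genes; use fewer chunks")
    col_of = {g: j for j, g in enumerate(genes)}

    joint_idx = {}
    offset = 0
    for s in sets:
        joint_idx[s.batch_names[0]] = np.arange(offset, offset + s.n_cells)
        offset += s.n_cells
    by_id = {s.batch_names[0]: s for s in sets}

    pool_idx = joint_idx[plan.anchor_batch_id].copy()
    corrected_rows = {i: joint.matrix[i].copy() for i in pool_idx}
    round_info = []
    for rnd, batch_id in enumerate(plan.order, start=1):
        src_idx = joint_idx[batch_id]
        rng = np.random.default_rng(_round_seed(root, "pairs_full", rnd))
        exact = config.use_exact(max(len(pool_idx), len(src_idx)))
        pairset, sub_src, sub_pool = build_rwmnn_pairs(
            codes[src_idx], codes[pool_idx], config.pair, rng, exact=exact,
            chain=config.walk_chain, deduplicate=config.deduplicate_pairs,
            batch_a_id=batch_id, batch_b_id="anchor_pool",
        )
        src_full = by_id[batch_id].matrix
        X_corr = np.empty_like(src_full)
        pool_X = np.vstack([corrected_rows[i] for i in pool_idx])
        info = {"batch": batch_id, "round": rnd, "n_seed_pairs": pairset.m_seeds,
                "n_pairs": len(pairset), "chunks": []}
        if len(pairset) == 0:
            warnings.warn(f"batch {batch_id!r}: no pairs; appended uncorrected")
            X_corr = src_full.copy()
        else:
            for ci, chunk in enumerate(partition.chunks):
                cols = np.array([col_of[g] for g in chunk])
                gan_seed = _round_seed(root, f"gan_full_{ci}", rnd)
                gan0 = build_gan(len(cols), seed=gan_seed, config=config.gan)
                gan, _log = train_stage2(
                    gan0, pairset,
                    X_source=src_full[sub_src][:, cols],
                    X_anchor=pool_X[sub_pool][:, cols],
                    epochs=stage2_epochs, seed=gan_seed,
                )
                X_corr[:, cols] = transform(gan, src_full[:, cols])
                info["chunks"].append({"chunk": ci, "n_genes": len(cols)})
        for row, i in enumerate(src_idx):
            corrected_rows[i] = X_corr[row]
        pool_idx = np.concatenate([pool_idx, src_idx])
        round_info.append(info)

    out_idx = np.concatenate([joint_idx[plan.anchor_batch_id]]
                             + [joint_idx[b] for b in plan.order])
    matrix = np.vstack([corrected_rows[i] for i in out_idx])
    corrected = ExpressionSet(
        matrix=matrix, cell_ids=joint.cell_ids[out_idx], gene_ids=joint.gene_ids,
        batch_labels=joint.batch_labels[out_idx],
        celltype_labels=None if joint.celltype_labels is None else joint.celltype_labels[out_idx],
        units=joint.units,
    )
    provenance = pd.DataFrame({
        "cell_id": joint.cell_ids[out_idx],
        "original_batch": joint.batch_labels[out_idx],
    })
    return IntegrationResult(corrected=corrected, provenance=provenance, plan=plan,
                             stage1_model=None, stage1_report=None,
                             codes=codes[out_idx], round_info=round_info)
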