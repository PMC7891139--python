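"""Desk-scale benchmark harness on the simulated `small` design.

One entry point per reported quantity, all fully seeded: end-to-end
correction quality (true-positive proportions before/after, batch-specific
cell survival), stage-I pair boost (MNN seed counts on content codes vs
raw log-TPM vectors), the random-walk ablation (m = 0 vs m = 50), and
probe-based recovery of planted genes. Network widths here are the
reduced benchmark widths (w1=256, w2=128, l=32, w3=128); production
defaults are larger.
"""

from __future__ import annotations

import numpy as np

from .data import concat_sets
from .evaluation import evaluate_mixing
from .integrate import IntegrationConfig, _canonical_sets, integrate_all
from .interpret import gene_importance, train_batch_probe, train_celltype_probe
from .io_prep import log_tpm_transform, qc_filter
from .pairs import PairParams, mutual_nn_pairs
from .simulate import default_benchmark_design, simulate
from .stage1 import Stage1Config, encode
from .stage2 import GanConfig

BENCH_WIDTHS = (256, 128)
BENCH_L = 32
BENCH_W3 = 128


def benchmark_config(stage1_epochs: int = 100, stage2_epochs: int = 100,
                     walk_m: int = 50) -> IntegrationConfig:
    """Reduced-width configuration used by the desk-scale benchmark."""
    return IntegrationConfig(
        stage1=Stage1Config(l=BENCH_L, widths=BENCH_WIDTHS, epochs=stage1_epochs),
        gan=GanConfig(l=BENCH_L, widths=BENCH_WIDTHS, w3=BENCH_W3,
                      epochs=stage2_epochs),
        pair=PairParams(m=walk_m),
    )


def prepared_small(seed: int):
    """Simulate the small two-batch design and preprocess to log-TPM."""
    es, truth = simulate(default_benchmark_design("small", seed=seed))
    logged = log_tpm_transform(qc_filter(es))
    return logged, truth


def _mixing_stats(es):
    report = evaluate_mixing(es.matrix, es.celltype_labels, es.batch_labels)
    table = report.table
    specific = table[table.celltype.isin(["C", "D"])]
    spec_pos = float(specific.label.isin(["false_positive", "true_positive"]).mean())
    return {
        "proportion_positive": report.proportion_positive,
        "proportion_true_positive": report.proportion_true_positive,
        "specific_positive_fraction": spec_pos,
    }


def run_small_benchmark(seed: int, walk_ms=(50, 0), stage1_epochs: int = 100,
                        stage2_epochs: int = 100) -> dict:
    """Full pipeline on the small design for one seed.

    Stage I is trained once and shared across the requested walk lengths;
    stage II is retrained per walk length. Returns uncorrected and
    per-walk corrected mixing statistics plus MNN seed-pair counts on
    stage-I codes and on raw log-TPM vectors.
    """
    logged, truth = prepared_small(seed)
    sets = list(logged.split_batches().values())
    out = {"seed": seed, "uncorrected": _mixing_stats(logged), "corrected": {}}

    stage1_model = None
    for m in walk_ms:
        cfg = benchmark_config(stage1_epochs, stage2_epochs, walk_m=m)
        res = integrate_all(sets, cfg, seed=seed, stage1_model=stage1_model)
        stage1_model = res.stage1_model
        stats = _mixing_stats(res.corrected)
        stats["n_seed_pairs"] = res.round_info[0]["n_seed_pairs"]
        stats["n_pairs"] = res.round_info[0]["n_pairs"]
        out["corrected"][m] = stats

    # pair boost: seeds on codes vs on raw expression, same k rule
    joint = concat_sets(_canonical_sets(sets))
    codes = encode(stage1_model, joint.matrix)
    b0 = joint.batch_labels == joint.batch_names[0]
    k = PairParams().resolve(int(b0.sum()), int((~b0).sum()))[1]
    out["seed_pairs_codes"] = mutual_nn_pairs(codes[~b0], codes[b0], k).m_seeds
    out["seed_pairs_raw"] = mutual_nn_pairs(joint.matrix[~b0], joint.matrix[b0],
                                            k).m_seeds
    out["stage1_model"] = stage1_model
    out["truth"] = truth
    out["logged"] = logged
    return out


def run_probe_recovery(seed: int, logged=None, truth=None,
                       stage1_model=None) -> dict:
    """Planted-gene recovery by the two probe classifiers.

    Returns the worst rank of the planted batch-diagnostic genes in
    batch-probe importance, and per-type worst ranks of planted markers
    in cell-type-probe importance (composed through the frozen encoder
    when one is supplied).
    """
    if logged is None:
        logged, truth = prepared_small(seed)
    X = logged.matrix
    rng = np.random.default_rng(seed)
    background = X[rng.choice(len(X), size=min(100, len(X)), replace=False)]

    batch_probe = train_batch_probe(X, logged.batch_labels, seed=seed)
    btab = gene_importance(batch_probe, X, background, gene_ids=logged.gene_ids)
    agg = btab.aggregate(np.zeros(len(X), int))[0].sort_values(ascending=False)
    order = list(agg.index)
    diag = [g for gs in truth.diag_genes.values() for g in gs]
    out = {
        "batch_probe_accuracy": batch_probe.holdout_accuracy,
        "diag_gene_worst_rank": max(order.index(g) for g in diag) + 1,
    }

    if stage1_model is not None:
        ct_probe = train_celltype_probe(stage1_model, X,
                                        logged.celltype_labels, seed=seed)
        ctab = gene_importance(ct_probe, X, background, gene_ids=logged.gene_ids)
        per_type = ctab.aggregate(logged.celltype_labels)
        worst = {}
        for t, markers in truth.markers.items():
            ranked = list(per_type[t].sort_values(ascending=False).index)
            worst[t] = max(ranked.index(g) for g in markers) + 1
        out["celltype_probe_accuracy"] = ct_probe.holdout_accuracy
        out["marker_worst_rank_per_type"] = worst
    return out
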