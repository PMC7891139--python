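"""Integration orchestration: planning, passthrough, provenance, chunking."""

import numpy as np
import pytest

from scstyle.data import concat_sets
from scstyle.integrate import (IntegrationConfig, integrate_all,
                               correct_full_transcriptome, plan_integration,
                               total_variance, _canonical_sets)
from scstyle.io_prep import log_tpm_transform, qc_filter
from scstyle.pairs import PairParams, PairSet
from scstyle.simulate import (BatchEffectSpec, SimulationDesign,
                              default_benchmark_design, simulate)
from scstyle.stage1 import Stage1Config, encode
from scstyle.stage2 import GanConfig

from conftest import make_set


def tiny_config(epochs1=6, epochs2=6):
    return IntegrationConfig(
        stage1=Stage1Config(l=4, widths=(16, 8), epochs=epochs1,
                            minibatch_size=64),
        gan=GanConfig(l=4, widths=(32, 16), w3=16, epochs=epochs2,
                      minibatch_size=64),
        pair=PairParams(m=5),
    )


def scaled_set(mult, batch, seed=0):
    rng = np.random.default_rng(seed)
    m = rng.random((20, 6)) * mult + 0.01
    return make_set(m, batches=[batch] * 20, units="log_tpm")


class TestPlan:
    def test_anchor_is_argmax_and_order_descending(self):
        a = scaled_set(10.0, "A")
        b = scaled_set(5.0, "B")
        c = scaled_set(1.0, "C")
        plan = plan_integration([c, a, b])
        assert plan.anchor_batch_id == "A"
        assert plan.order == ["B", "C"]
        assert plan.variances["A"] == pytest.approx(total_variance(a))

    def test_override_anchor(self):
        a, b, c = scaled_set(10.0, "A"), scaled_set(5.0, "B"), scaled_set(1.0, "C")
        plan = plan_integration([a, b, c], override_anchor="C")
        assert plan.anchor_batch_id == "C"
        assert set(plan.order) == {"A", "B"}
        assert plan.user_override

    def test_override_order(self):
        a, b, c = scaled_set(10.0, "A"), scaled_set(5.0, "B"), scaled_set(1.0, "C")
        plan = plan_integration([a, b, c], override_order=["C", "B"])
        assert plan.order == ["C", "B"]

    def test_unknown_override_rejected(self):
        a, b = scaled_set(2.0, "A"), scaled_set(1.0, "B")
        with pytest.raises(ValueError, match="not an input batch"):
            plan_integration([a, b], override_anchor="Z")
        with pytest.raises(ValueError, match="unknown"):
            plan_integration([a, b], override_order=["Z"])

    def test_equal_variance_tie_is_lexicographic_and_stable(self):
        base = np.random.default_rng(0).random((20, 6)) + 0.01
        a = make_set(base, batches=["zz"] * 20, units="log_tpm")
        b = make_set(base.copy(), batches=["aa"] * 20, units="log_tpm")
        b = type(b)(b.matrix, np.array([f"o{i}" for i in range(20)], object),
                    b.gene_ids, b.batch_labels, units="log_tpm")
        for _ in range(3):
            plan = plan_integration([a, b])
            assert plan.anchor_batch_id == "aa"

    def test_input_order_invariance(self):
        a, b, c = scaled_set(10.0, "A"), scaled_set(5.0, "B"), scaled_set(1.0, "C")
        p1 = plan_integration([a, b, c])
        p2 = plan_integration([c, b, a])
        assert (p1.anchor_batch_id, p1.order) == (p2.anchor_batch_id, p2.order)


@pytest.fixture(scope="module")
def tiny_sets():
    es, _ = simulate(default_benchmark_design("tiny", seed=21))
    logged = log_tpm_transform(qc_filter(es))
    return list(logged.split_batches().values())


@pytest.fixture(scope="module")
def tiny_result(tiny_sets):
    return integrate_all(tiny_sets, tiny_config(), seed=5)


class TestIntegrateAll:
    def test_anchor_passthrough_bit_exact(self, tiny_sets, tiny_result):
        res = tiny_result
        anchor_id = res.plan.anchor_batch_id
        anchor_in = next(s for s in tiny_sets if s.batch_names[0] == anchor_id)
        mask = res.corrected.batch_labels == anchor_id
        out_rows = {c: r for c, r in zip(res.corrected.cell_ids[mask],
                                         res.corrected.matrix[mask])}
        for cid, row in zip(anchor_in.cell_ids, anchor_in.matrix):
            np.testing.assert_array_equal(out_rows[cid], row)

    def test_cell_conservation(self, tiny_sets, tiny_result):
        total = sum(s.n_cells for s in tiny_sets)
        assert tiny_result.corrected.n_cells == total
        assert len(set(tiny_result.corrected.cell_ids)) == total

    def test_output_nonnegative_and_finite(self, tiny_result):
        m = tiny_result.corrected.matrix
        assert np.isfinite(m).all() and m.min() >= 0.0

    def test_provenance_bookkeeping(self, tiny_result):
        prov = tiny_result.provenance
        anchor_id = tiny_result.plan.anchor_batch_id
        assert (prov.loc[prov.original_batch == anchor_id, "round"] == 0).all()
        assert not prov.loc[prov.original_batch == anchor_id, "corrected"].any()
        assert prov.loc[prov.original_batch != anchor_id, "corrected"].all()

    def test_three_batches_train_two_gans_in_plan_order(self):
        design = SimulationDesign(
            n_batches=3, n_genes=40,
            cell_counts={"A": [25, 25, 25], "B": [25, 25, 25]},
            batch_effects=[BatchEffectSpec(),
                           BatchEffectSpec(shift_sigma=0.5),
                           BatchEffectSpec(shift_sigma=0.8)],
            n_markers_per_type=3, seed=33,
        )
        es, _ = simulate(design)
        sets = list(log_tpm_transform(qc_filter(es)).split_batches().values())
        res = integrate_all(sets, tiny_config(epochs1=4, epochs2=4), seed=2)
        assert len(res.round_info) == 2
        assert [i["batch"] for i in res.round_info] == res.plan.order

    def test_seeded_reproducibility_under_input_permutation(self, tiny_sets):
        cfg = tiny_config(epochs1=3, epochs2=3)
        r1 = integrate_all(list(tiny_sets), cfg, seed=8)
        r2 = integrate_all(list(reversed(tiny_sets)), cfg, seed=8)
        np.testing.assert_array_equal(r1.corrected.matrix, r2.corrected.matrix)
        assert list(r1.corrected.cell_ids) == list(r2.corrected.cell_ids)

    def test_zero_pair_fallback_appends_uncorrected(self, tiny_sets, monkeypatch):
        import scstyle.integrate as integ

        def no_pairs(codes_a, codes_b, params, rng, **kw):
            empty = PairSet(np.empty((0, 2), int), np.array([], object),
                            np.array([], int))
            return empty, np.arange(len(codes_a)), np.arange(len(codes_b))

        monkeypatch.setattr(integ, "build_rwmnn_pairs", no_pairs)
        with pytest.warns(UserWarning, match="appended uncorrected"):
            res = integrate_all(tiny_sets, tiny_config(epochs1=2, epochs2=2), seed=1)
        assert not res.provenance.corrected.any()
        joint = concat_sets(_canonical_sets(tiny_sets))
        rows = {c: r for c, r in zip(joint.cell_ids, joint.matrix)}
        for cid, row in zip(res.corrected.cell_ids, res.corrected.matrix):
            np.testing.assert_array_equal(row, rows[cid])


class TestFullTranscriptome:
    def test_chunked_correction_preserves_gene_order(self, tiny_sets):
        cfg = tiny_config(epochs1=3, epochs2=2)
        base = integrate_all(tiny_sets, cfg, seed=4)
        joint = concat_sets(_canonical_sets(tiny_sets))
        codes = encode(base.stage1_model, joint.matrix)
        res = correct_full_transcriptome(tiny_sets, codes, base.plan,
                                         n_chunks=2, config=cfg, seed=4,
                                         stage2_epochs=2)
        assert list(res.corrected.gene_ids) == list(joint.gene_ids)
        assert res.corrected.n_cells == joint.n_cells
        assert res.corrected.matrix.min() >= 0.0
        anchor_id = base.plan.anchor_batch_id
        mask = res.corrected.batch_labels == anchor_id
        assert len(res.round_info[0]["chunks"]) == 2

    def test_tiny_chunks_rejected(self, tiny_sets):
        cfg = tiny_config()
        base_plan = plan_integration(tiny_sets)
        joint = concat_sets(_canonical_sets(tiny_sets))
        with pytest.raises(ValueError, match="fewer chunks"):
            correct_full_transcriptome(tiny_sets, np.zeros((joint.n_cells, 4)),
                                       base_plan, n_chunks=60, config=cfg, seed=0)


def test_integrate_requires_two_batches():
    a = scaled_set(1.0, "A")
    with pytest.raises(ValueError):
        plan_integration([a])
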