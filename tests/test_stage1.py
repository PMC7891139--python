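"""Stage-I disentangling autoencoder: formulas, training, determinism."""

import autograd
import numpy as np
import pytest

from scstyle import nnet
from scstyle.stage1 import (Stage1Config, build_stage1, content_loss, encode,
                            one_hot, reconstruct, reconstruction_loss,
                            sample_random_batch_indicator, train_stage1,
                            _stage1_update_grads, _total_loss)


def tiny_model(d=10, n=2, l=2, widths=(8, 4), seed=0, activation="mish"):
    return build_stage1(d, n, config=Stage1Config(l=l, widths=widths,
                                                  activation=activation), seed=seed)


def identity_stage1(d=3):
    """Linear-activation construction with E = identity and G(c, b) = c.

    Both losses evaluate to exactly zero on non-negative input: the
    encoder passes x through unchanged and the generators rebuild it for
    any batch indicator.
    """
    m = build_stage1(d, 2, config=Stage1Config(l=d, widths=(d, d),
                                               activation="linear"), seed=0)
    eye = np.eye(d)
    for net in (m.encoder, m.g1, m.g2):
        for W, b in net:
            W[:] = 0.0
            b[:] = 0.0
    for layer in m.encoder:
        layer[0][:] = eye
    # G2 reads (c, b): wire the code part straight through
    m.g2[0][0][:d, :] = eye
    m.g2[1][0][:] = eye
    m.g2[2][0][:] = eye
    return m


class TestBuild:
    def test_shapes_follow_spec_layout(self):
        m = build_stage1(2000, 2, l=256, widths=(1024, 512), seed=0)
        assert [w.shape for w, _ in m.encoder] == [(2000, 1024), (1024, 512), (512, 256)]
        assert [w.shape for w, _ in m.g1] == [(2, 512), (512, 1024), (1024, 2000)]
        assert [w.shape for w, _ in m.g2] == [(258, 512), (512, 1024), (1024, 2000)]

    def test_seed_determinism(self):
        assert nnet.tree_equal(tiny_model(seed=4).params(), tiny_model(seed=4).params())

    def test_tiny_forward_finite(self):
        m = tiny_model()
        x = np.abs(np.random.default_rng(0).standard_normal((3, 10)))
        b = one_hot([0, 1, 0], 2)
        out = reconstruct(m, x, b)
        assert out.shape == (3, 10) and np.isfinite(out).all()

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            build_stage1(0, 2)


class TestReconstruct:
    def test_output_nonnegative(self):
        m = tiny_model(seed=1)
        rng = np.random.default_rng(2)
        x = np.abs(rng.standard_normal((20, 10))) * 5
        out = reconstruct(m, x, one_hot(rng.integers(0, 2, 20), 2))
        assert out.min() >= 0.0

    def test_zeroed_networks_give_zero_output(self):
        m = tiny_model(seed=0)
        for net in (m.g1, m.g2):
            for W, b in net:
                W[:] = 0
                b[:] = 0
        out = reconstruct(m, np.ones((2, 10)), one_hot([0, 1], 2))
        np.testing.assert_array_equal(out, np.zeros((2, 10)))

    def test_matches_explicit_loop_replay(self):
        """Independent re-computation of the composed map on a frozen net."""
        m = tiny_model(d=4, l=2, widths=(3, 3), seed=7)
        x = np.array([[0.5, 1.0, 0.0, 2.0]])
        b = one_hot([1], 2)

        def mish(v):
            return v * np.tanh(np.log1p(np.exp(v)))

        def run(net, inp):
            h = inp
            for i, (W, bias) in enumerate(net):
                h = h @ W + bias
                if i < len(net) - 1:
                    h = mish(h)
            return h

        c = run(m.encoder, x)
        expected = np.maximum(run(m.g1, b) + run(m.g2, np.hstack([c, b])), 0.0)
        np.testing.assert_allclose(reconstruct(m, x, b), expected, atol=1e-10)

    def test_dimension_mismatch(self):
        m = tiny_model()
        with pytest.raises(ValueError):
            reconstruct(m, np.ones((1, 3)), one_hot([0], 2))


class TestLosses:
    def test_identity_construction_zero_losses(self):
        m = identity_stage1(d=3)
        x = np.abs(np.random.default_rng(1).standard_normal((6, 3)))
        b = one_hot([0, 1, 0, 1, 0, 1], 2)
        bt = one_hot([1, 1, 0, 0, 1, 0], 2)
        assert reconstruction_loss(m, x, b) == 0.0
        assert content_loss(m, x, bt) == 0.0

    def test_zero_reconstruction_hand_values(self):
        m = tiny_model(d=2, l=1, widths=(2, 2))
        for net in (m.g1, m.g2):
            for W, bias in net:
                W[:] = 0
                bias[:] = 0
        # rec == 0: ||0 - (1,1)||^2 = 2 ; two-cell batch (2 and 4) -> mean 3
        assert reconstruction_loss(m, np.array([[1.0, 1.0]]), one_hot([0], 2)) == 2.0
        x2 = np.array([[1.0, 1.0], [2.0, 0.0]])
        assert reconstruction_loss(m, x2, one_hot([0, 1], 2)) == pytest.approx(3.0)

    def test_content_loss_hand_offset(self):
        # identity encoder; G2 adds (3, 4) to the code -> L_c = 25
        m = identity_stage1(d=2)
        m.g2[-1][1][:] = np.array([3.0, 4.0])
        x = np.abs(np.random.default_rng(0).standard_normal((5, 2))) + 1.0
        assert content_loss(m, x, one_hot([0] * 5, 2)) == pytest.approx(25.0)

    def test_content_loss_equals_double_forward_recomputation(self):
        m = tiny_model(d=6, l=3, widths=(5, 4), seed=3)
        rng = np.random.default_rng(5)
        x = np.abs(rng.standard_normal((3, 6)))
        bt = one_hot(rng.integers(0, 2, 3), 2)
        got = content_loss(m, x, bt)
        c = encode(m, x)
        fab = reconstruct(m, x, bt)
        c2 = encode(m, fab)
        expect = float(np.mean(np.sum((c2 - c) ** 2, axis=1)))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_manual_gradient_matches_autograd(self):
        m = tiny_model(d=7, n=3, l=2, widths=(5, 4), seed=2)
        rng = np.random.default_rng(3)
        x = np.abs(rng.standard_normal((4, 7)))
        b = one_hot(rng.integers(0, 3, 4), 3)
        bt = one_hot(rng.integers(0, 3, 4), 3)
        l_r, l_c, grads = _stage1_update_grads(m, m.params(), x, b, bt, 3.0, 1.0)
        val, a_grads = autograd.value_and_grad(_total_loss)(
            m.params(), m, x, b, bt, 3.0, 1.0)
        assert 3.0 * l_c + l_r == pytest.approx(val, rel=1e-12)
        diffs = []
        nnet.tree_map(lambda a, c: diffs.append(np.max(np.abs(a - c))), grads, a_grads)
        assert max(diffs) < 1e-10


class TestRandomIndicator:
    def test_single_batch(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(
            sample_random_batch_indicator(1, rng, size=4), np.ones((4, 1)))

    def test_uniform_frequencies(self):
        rng = np.random.default_rng(1)
        draws = sample_random_batch_indicator(3, rng, size=30000)
        freqs = draws.mean(axis=0)
        assert np.all((freqs > 0.32) & (freqs < 0.35))

    def test_seeded_sequence(self):
        a = sample_random_batch_indicator(4, np.random.default_rng(5), size=10)
        b = sample_random_batch_indicator(4, np.random.default_rng(5), size=10)
        np.testing.assert_array_equal(a, b)


class TestTraining:
    def test_loss_descends_on_tiny_fixture(self, tiny_logged):
        es, _ = tiny_logged
        finals, initials = [], []
        for seed in range(3):
            m = build_stage1(es.n_genes, 2,
                             config=Stage1Config(l=4, widths=(16, 8)), seed=seed)
            _, rep = train_stage1(m, es, epochs=30, minibatch_size=64, seed=seed)
            initials.append(rep.total_loss.iloc[0])
            finals.append(rep.total_loss.iloc[-1])
        assert np.median(finals) < np.median(initials)

    def test_zero_epochs_noop(self, tiny_logged):
        es, _ = tiny_logged
        m = build_stage1(es.n_genes, 2, config=Stage1Config(l=4, widths=(16, 8)))
        out, rep = train_stage1(m, es, epochs=0)
        assert rep.empty
        assert nnet.tree_equal(out.params(), m.params())

    def test_training_determinism(self, tiny_logged):
        es, _ = tiny_logged
        def run():
            m = build_stage1(es.n_genes, 2,
                             config=Stage1Config(l=4, widths=(16, 8)), seed=1)
            return train_stage1(m, es, epochs=5, minibatch_size=64, seed=9)
        m1, r1 = run()
        m2, r2 = run()
        assert nnet.tree_equal(m1.params(), m2.params())
        assert r1.equals(r2)

    def test_disentanglement_reduces_cross_batch_code_distance(self, tiny_logged):
        """After training, same-type cells from different batches sit closer
        in code space than under the untrained encoder."""
        es, _ = tiny_logged
        ratios = []
        for seed in range(3):
            m0 = build_stage1(es.n_genes, 2,
                              config=Stage1Config(l=8, widths=(32, 16)), seed=seed)
            m1, _ = train_stage1(m0, es, epochs=40, minibatch_size=32, seed=seed)

            def cross_dist(model):
                codes = encode(model, es.matrix)
                codes = codes / (np.linalg.norm(codes, axis=1, keepdims=True) + 1e-12)
                vals = []
                for t in set(es.celltype_labels):
                    m_a = (es.celltype_labels == t) & (es.batch_labels == "batch0")
                    m_b = (es.celltype_labels == t) & (es.batch_labels == "batch1")
                    vals.append(np.linalg.norm(codes[m_a].mean(0) - codes[m_b].mean(0)))
                return np.mean(vals)

            ratios.append(cross_dist(m1) / cross_dist(m0))
        assert np.median(ratios) < 1.0


class TestEncode:
    def test_duplicate_rows_and_stacking(self):
        m = tiny_model(seed=5)
        x = np.abs(np.random.default_rng(6).standard_normal((4, 10)))
        codes = encode(m, x)
        stacked = encode(m, np.vstack([x, x]))
        np.testing.assert_array_equal(stacked[:4], codes)
        np.testing.assert_array_equal(stacked[4:], codes)

    def test_batched_equals_looped(self):
        m = tiny_model(seed=6)
        x = np.abs(np.random.default_rng(7).standard_normal((5, 10)))
        batched = encode(m, x)
        looped = np.vstack([encode(m, x[i]) for i in range(5)])
        np.testing.assert_allclose(batched, looped, atol=1e-12)

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            encode(tiny_model(), np.ones((2, 3)))
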