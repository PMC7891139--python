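"""Stage-II GAN: shortcut identity, WGAN-GP formulas, training contracts."""

import autograd
import numpy as np
import pytest

from scstyle import nnet
from scstyle.pairs import PairSet
from scstyle.stage2 import (GanConfig, build_gan, critic_objective,
                            train_stage2, transform, _critic_loss_scalar,
                            _critic_update_grads, _gen_update_grads)


def tiny_gan(d=8, l=2, widths=(6, 4), w3=5, seed=0, activation="mish", **kw):
    return build_gan(d, config=GanConfig(l=l, widths=widths, w3=w3,
                                         activation=activation, **kw), seed=seed)


def zero_residual(model):
    for W, b in model.gen:
        W[:] = 0.0
        b[:] = 0.0
    return model


def make_pairs(n):
    idx = np.arange(n)
    return PairSet(np.column_stack([idx, idx]),
                   np.array(["seed"] * n, object), np.zeros(n, int))


class TestBuildAndTransform:
    def test_generator_nonnegative_at_origin(self):
        m = tiny_gan(seed=3)
        out = transform(m, np.zeros((1, 8)))
        assert out.min() >= 0.0

    def test_zero_residual_is_identity_on_nonnegative(self):
        m = zero_residual(tiny_gan(seed=1))
        x = np.abs(np.random.default_rng(0).standard_normal((5, 8)))
        np.testing.assert_array_equal(transform(m, x), x)

    def test_seed_determinism(self):
        assert nnet.tree_equal(tiny_gan(seed=9).gen, tiny_gan(seed=9).gen)
        assert nnet.tree_equal(tiny_gan(seed=9).critic, tiny_gan(seed=9).critic)

    def test_fresh_generator_starts_at_identity(self):
        """The residual output layer is zero-initialized."""
        m = tiny_gan(seed=4)
        x = np.abs(np.random.default_rng(1).standard_normal((6, 8)))
        np.testing.assert_allclose(transform(m, x), x, atol=1e-12)

    def test_row_independence_and_shape(self):
        m = tiny_gan(seed=5)
        m.gen[-1][0][:] = np.random.default_rng(2).standard_normal(
            m.gen[-1][0].shape) * 0.1
        x = np.abs(np.random.default_rng(3).standard_normal((4, 8)))
        out = transform(m, x)
        assert out.shape == x.shape
        stacked = transform(m, np.vstack([x, x]))
        np.testing.assert_array_equal(stacked[:4], out)
        np.testing.assert_array_equal(stacked[4:], out)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            transform(tiny_gan(), np.ones((2, 3)))


class TestCriticObjective:
    def test_constant_critic_gp_is_one(self):
        m = tiny_gan(seed=0)
        for W, b in m.critic:
            W[:] = 0.0
            b[:] = 0.0
        rng = np.random.default_rng(1)
        xr, xf = rng.random((6, 8)), rng.random((6, 8))
        loss, gp = critic_objective(m, xr, xf, gp_weight=10.0, rng=rng)
        assert gp == pytest.approx(1.0, abs=1e-5)
        assert loss == pytest.approx(10.0, abs=1e-4)

    def test_unit_gradient_linear_critic_zero_penalty(self):
        """D(x) = w . x with ||w|| = 1 has unit input gradient everywhere."""
        m = tiny_gan(seed=0, activation="linear")
        (W1, b1), (W2, b2), (W3, b3) = m.critic
        W1[:] = 0.0
        W1[0, 0] = 1.0          # route x_0 through
        W2[:] = 0.0
        W2[0, 0] = 1.0
        W3[:] = 0.0
        W3[0, 0] = 1.0
        b1[:] = b2[:] = b3[:] = 0.0
        rng = np.random.default_rng(2)
        _, gp = critic_objective(m, rng.random((5, 8)), rng.random((5, 8)),
                                 gp_weight=10.0, rng=rng)
        assert gp == pytest.approx(0.0, abs=1e-24)

    def test_matches_hand_rolled_finite_difference_recomputation(self):
        """Independent recomputation: explicit formula with numerical
        input gradients on a frozen 4-sample fixture."""
        m = tiny_gan(d=6, l=2, widths=(5, 4), w3=4, seed=8)
        rng = np.random.default_rng(9)
        xr = rng.random((4, 6))
        xf = rng.random((4, 6))
        eps = rng.random((4, 1))
        loss, gp = critic_objective(m, xr, xf, gp_weight=10.0, eps=eps)

        def D(v):
            h = v
            for i, (W, b) in enumerate(m.critic):
                h = h @ W + b
                if i < 2:
                    h = h * np.tanh(np.log1p(np.exp(h)))
            return h[:, 0]

        wasserstein = D(xf).mean() - D(xr).mean()
        interp = eps * xr + (1 - eps) * xf
        h = 1e-6
        norms = []
        for i in range(4):
            g = np.array([(D(interp[i:i + 1] + h * np.eye(6)[j:j + 1])
                           - D(interp[i:i + 1] - h * np.eye(6)[j:j + 1]))[0] / (2 * h)
                          for j in range(6)])
            norms.append(np.linalg.norm(g))
        gp_expect = np.mean((np.array(norms) - 1.0) ** 2)
        assert gp == pytest.approx(gp_expect, abs=1e-5)
        assert loss == pytest.approx(wasserstein + 10.0 * gp_expect, abs=1e-4)

    def test_manual_update_gradients_match_autograd(self):
        m = tiny_gan(d=7, l=3, widths=(6, 5), w3=6, seed=11)
        rng = np.random.default_rng(12)
        m.gen[-1][0][:] = rng.standard_normal(m.gen[-1][0].shape) * 0.1
        xr, xf = rng.random((5, 7)), rng.random((5, 7))
        eps = rng.random((5, 1))
        loss_m, _, grads_m = _critic_update_grads(m, m.critic, xr, xf, eps, 10.0)
        loss_a, grads_a = autograd.value_and_grad(_critic_loss_scalar)(
            m.critic, m, xr, xf, eps, 10.0)
        assert loss_m == pytest.approx(loss_a, rel=1e-12)
        diffs = []
        nnet.tree_map(lambda a, b: diffs.append(np.max(np.abs(a - b))),
                      grads_m, grads_a)
        assert max(diffs) < 1e-10


class TestTraining:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        anchor = np.abs(rng.standard_normal((40, 8))) + 1.0
        source = anchor[rng.permutation(40)] + 2.0   # constant shift
        return source, anchor, make_pairs(40)

    def test_zero_epochs_noop(self):
        src, anc, pairs = self._fixture()
        m = tiny_gan(seed=2)
        out, log = train_stage2(m, pairs, src, anc, epochs=0)
        assert log.empty
        assert nnet.tree_equal(out.gen, m.gen)

    def test_training_determinism(self):
        src, anc, pairs = self._fixture()
        def run():
            m = tiny_gan(seed=3, epochs=4, minibatch_size=16)
            return train_stage2(m, pairs, src, anc, seed=7)
        m1, l1 = run()
        m2, l2 = run()
        assert nnet.tree_equal(m1.gen, m2.gen)
        assert l1.equals(l2)

    def test_critic_gap_shrinks_on_shifted_fixture(self):
        """After the critic warms up, the adversarial gap collapses as the
        generator closes the constant shift."""
        ratios = []
        for seed in range(3):
            src, anc, pairs = self._fixture(seed)
            m = tiny_gan(d=8, l=2, widths=(16, 8), w3=8, seed=seed,
                         epochs=200, minibatch_size=20)
            trained, log = train_stage2(m, pairs, src, anc, seed=seed)
            windows = np.array_split(log.critic_loss.to_numpy(), 10)
            means = [np.abs(w).mean() for w in windows]
            ratios.append(means[-1] / max(means))
        assert np.median(ratios) < 0.5

    def test_shifted_source_moves_toward_anchor(self):
        """Distribution matching on a constant gene-wise shift."""
        deltas = []
        for seed in range(3):
            src, anc, pairs = self._fixture(seed)
            m = tiny_gan(d=8, l=2, widths=(16, 8), w3=8, seed=seed,
                         epochs=200, minibatch_size=20)
            trained, _ = train_stage2(m, pairs, src, anc, seed=seed)
            corrected = transform(trained, src)
            before = np.linalg.norm(src.mean(0) - anc.mean(0))
            after = np.linalg.norm(corrected.mean(0) - anc.mean(0))
            deltas.append(after / before)
        assert np.median(deltas) < 1.0

    def test_corrected_output_nonnegative(self):
        src, anc, pairs = self._fixture(1)
        m = tiny_gan(seed=1, epochs=5, minibatch_size=16)
        trained, _ = train_stage2(m, pairs, src, anc, seed=1)
        assert transform(trained, src).min() >= 0.0

    def test_empty_pairs_rejected(self):
        m = tiny_gan()
        empty = PairSet(np.empty((0, 2), int), np.array([], object),
                        np.array([], int))
        with pytest.raises(ValueError):
            train_stage2(m, empty, np.ones((2, 8)), np.ones((2, 8)))

    def test_pair_indices_validated(self):
        m = tiny_gan()
        pairs = make_pairs(5)
        with pytest.raises(IndexError):
            train_stage2(m, pairs, np.ones((3, 8)), np.ones((5, 8)))
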