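"""Stage II: adversarial removal of batch effects from expression profiles.

A residual-shortcut generator G'(x) = f(F(x) + x) (f elementwise ReLU, F
an autoencoder-shaped network) learns to move source-batch cells into the
anchor batch's style, against a critic D' trained under the WGAN-GP
objective. Training data are exclusively the rwMNN pairs: the batch-A
member feeds the generator, the batch-B (anchor) member is the critic's
"real" sample. After training, every source cell — paired or not — is
transformed by the generator.

The critic loss is

    mean D'(G'(x1)) - mean D'(x2)
      + gp_weight * mean (||grad D'(x_hat)|| - 1)^2

with x_hat uniform on segments between paired real and generated samples;
the generator minimizes -mean D'(G'(x1)).

Numerical conditioning: by default training runs in gene-standardized
coordinates x~ = (x - mu) / sigma (mu, sigma estimated from the cells the
pairs reference). This is an exact reparametrization of the same model
family — G'(x) = relu(F(x) + x) with F(x) = sigma * F~(x~) — but the
critic's Lipschitz ball, and hence the transport metric, weighs every
gene equally instead of being dominated by high-expression genes. The
fitted mean/scale are stored on the model so ``transform`` is
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd
import autograd.numpy as anp
import numpy as np
import pandas as pd

from . import nnet
from .nnet import Adam, get_activation, init_mlp, linear, mlp_forward
from .pairs import PairSet


@dataclass
class GanConfig:
    l: int = 256
    widths: tuple = (1024, 512)
    w3: int = 512
    learning_rate: float = 2e-4
    critic_learning_rate: float | None = 4e-4    # None: same as learning_rate
    betas: tuple = (0.5, 0.999)
    gp_weight: float = 10.0
    critic_steps: int = 2
    minibatch_size: int = 512
    epochs: int = 150
    activation: str = "mish"
    standardize: bool = True


@dataclass
class GanModel:
    """Parameter container for the generator residual F and critic D'.

    ``x_mean`` / ``x_scale`` hold the gene-wise standardization fitted at
    training time (identity when None).
    """

    gen: list                          # F~: d->w1->w2->l->w2->w1->d
    critic: list                       # D': d->w3->w3->1
    d: int
    config: GanConfig = field(default_factory=GanConfig)
    seed: int = 0
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    def _gen_act_names(self):
        """Hidden layers of F carry the activation, except the linear
        bottleneck; the output layer is linear so the residual F(x) can
        subtract as well as add expression (a bounded-below output
        activation could never undo a positive batch shift)."""
        n = len(self.gen)
        return ["linear" if i in (n // 2 - 1, n - 1) else self.config.activation
                for i in range(n)]

    def _gen_acts(self):
        return [get_activation(a) for a in self._gen_act_names()]

    def _critic_act_names(self):
        return [self.config.activation] * (len(self.critic) - 1) + ["linear"]

    def _critic_acts(self):
        return [get_activation(a) for a in self._critic_act_names()]

    # -- standardization helpers ---------------------------------------
    @property
    def mu(self) -> np.ndarray:
        return np.zeros(self.d) if self.x_mean is None else self.x_mean

    @property
    def sc(self) -> np.ndarray:
        return np.ones(self.d) if self.x_scale is None else self.x_scale

    @property
    def lo(self) -> np.ndarray:
        """Scaled-space floor corresponding to zero expression."""
        return -self.mu / self.sc

    def to_scaled(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sc

    def from_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.sc + self.mu


def build_gan(d: int, l: int = 256, widths: tuple = (1024, 512), w3: int = 512,
              seed: int = 0, config: GanConfig | None = None) -> GanModel:
    """Seeded initialization of G' (via its residual F) and D'."""
    if config is None:
        config = GanConfig(l=l, widths=tuple(widths), w3=w3)
    l, (w1, w2), w3 = config.l, config.widths, config.w3
    if min(d, l, w1, w2, w3) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    gen = init_mlp([d, w1, w2, l, w2, w1, d], rng)
    # zero output layer: G'(x) = relu(F(x) + x) starts as the identity on
    # non-negative input, so untrained cells pass through unchanged and the
    # generator only learns critic-driven deviations from the identity
    gen[-1][0][:] = 0.0
    critic = init_mlp([d, w3, w3, 1], rng)
    return GanModel(gen, critic, d=d, config=config, seed=seed)


# ---------------------------------------------------------------------------
# forward maps (scaled coordinates)
# ---------------------------------------------------------------------------

def _generator_scaled(gen_params, model: GanModel, xs, lo):
    """F~(x~) + x~ floored at the scaled-space image of zero expression."""
    return anp.maximum(mlp_forward(gen_params, xs, model._gen_acts()) + xs, lo)


def _critic(critic_params, model: GanModel, xs):
    return mlp_forward(critic_params, xs, model._critic_acts())[:, 0]


def transform(model: GanModel, X: np.ndarray) -> np.ndarray:
    """Row-wise G' application; non-negative output, shape preserved."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"generator expects {model.d} genes, got {X.shape[1]}")
    out_s = _generator_scaled(model.gen, model, model.to_scaled(X), model.lo)
    # the floor maps back to exactly zero expression up to float rounding
    return np.maximum(model.from_scaled(np.asarray(out_s)), 0.0)


def critic_scores(model: GanModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.asarray(_critic(model.critic, model, model.to_scaled(X)))


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def _critic_loss(critic_params, model, xs_real, xs_fake, eps, gp_weight):
    scores = _critic(critic_params, model, anp.concatenate([xs_real, xs_fake], axis=0))
    n = xs_real.shape[0]
    wasserstein = anp.mean(scores[n:]) - anp.mean(scores[:n])
    interp = eps * xs_real + (1.0 - eps) * xs_fake

    def total_score(xi):
        return anp.sum(_critic(critic_params, model, xi))

    g = autograd.grad(total_score)(interp)
    norms = anp.sqrt(anp.sum(g * g, axis=1) + 1e-12)
    gp = anp.mean((norms - 1.0) ** 2)
    return wasserstein + gp_weight * gp, (wasserstein, gp)


def _critic_loss_scalar(critic_params, model, xs_real, xs_fake, eps, gp_weight):
    return _critic_loss(critic_params, model, xs_real, xs_fake, eps, gp_weight)[0]


def _gen_loss(gen_params, critic_params, model, xs_source, lo):
    fake = _generator_scaled(gen_params, model, xs_source, lo)
    return -anp.mean(_critic(critic_params, model, fake))


def _critic_update_grads(model: GanModel, critic, xs_real, xs_fake, eps, gp_weight):
    """Manual gradient of the critic loss; returns (loss, gp, grads)."""
    acts = model._critic_act_names()
    n = xs_real.shape[0]
    both = np.vstack([xs_real, xs_fake])
    scores, cache = nnet.forward_cache(critic, both, acts)
    wasserstein = float(scores[n:].mean() - scores[:n].mean())
    gout = np.full((2 * n, 1), 1.0 / n)
    gout[:n] *= -1.0
    grads, _ = nnet.backward(critic, cache, acts, gout)

    interp = eps * xs_real + (1.0 - eps) * xs_fake
    g, aux = nnet.input_gradient_2h(critic, interp, acts)
    norms = np.sqrt((g * g).sum(axis=1) + 1e-12)
    gp = float(np.mean((norms - 1.0) ** 2))
    r = (gp_weight / n) * (2.0 * (norms - 1.0) / norms)[:, None] * g
    gp_grads = nnet.gp_param_grads_2h(critic, interp, acts, r, aux)
    grads = nnet.tree_map(np.add, grads, gp_grads)
    return wasserstein + gp_weight * gp, gp, grads


def _gen_update_grads(model: GanModel, gen, critic, xs_source, lo):
    """Manual gradient of -mean D'(G'(x)); returns (loss, grads)."""
    gen_acts = model._gen_act_names()
    critic_acts = model._critic_act_names()
    n = xs_source.shape[0]
    f_out, gen_cache = nnet.forward_cache(gen, xs_source, gen_acts)
    pre = f_out + xs_source
    fake = np.maximum(pre, lo)
    scores, c_cache = nnet.forward_cache(critic, fake, critic_acts)
    loss = -float(scores.mean())
    gout = np.full((n, 1), -1.0 / n)
    _, g_fake = nnet.backward(critic, c_cache, critic_acts, gout)
    g_pre = g_fake * (pre > lo)
    grads, _ = nnet.backward(gen, gen_cache, gen_acts, g_pre)
    return loss, grads


def critic_objective(model: GanModel, x_real: np.ndarray, x_fake: np.ndarray,
                     gp_weight: float | None = None,
                     rng: np.random.Generator | None = None,
                     eps: np.ndarray | None = None) -> tuple[float, float]:
    """Evaluate the WGAN-GP critic loss and its gradient-penalty term.

    ``x_real`` / ``x_fake`` are expression-space sample blocks; on a
    standardized model they are mapped into the critic's (scaled)
    coordinates first (identity for a freshly built model). Interpolates
    are drawn uniformly on segments between paired real and fake samples
    (supply ``eps`` to pin them). Returns (loss, gp value) where loss
    already includes ``gp_weight * gp``.
    """
    x_real = np.atleast_2d(np.asarray(x_real, float))
    x_fake = np.atleast_2d(np.asarray(x_fake, float))
    if x_real.shape != x_fake.shape:
        raise ValueError("real and fake sample blocks must have equal shapes")
    if gp_weight is None:
        gp_weight = model.config.gp_weight
    if eps is None:
        rng = rng or np.random.default_rng()
        eps = rng.random((x_real.shape[0], 1))
    loss, (_, gp) = _critic_loss(model.critic, model, model.to_scaled(x_real),
                                 model.to_scaled(x_fake),
                                 np.asarray(eps, float), gp_weight)
    return float(loss), float(gp)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_stage2(model: GanModel, pairs: PairSet, X_source: np.ndarray,
                 X_anchor: np.ndarray, epochs: int | None = None,
                 minibatch_size: int | None = None, seed: int = 0):
    """Alternating WGAN-GP optimization on the rwMNN pair list.

    Pairs (not cells) are the sampling unit: each update draws a pair
    minibatch uniformly with replacement, feeding the source member to G'
    and the anchor member to D' as real. One epoch is
    ceil(|pairs| / minibatch) generator updates, each preceded by
    ``critic_steps`` critic updates. Returns the trained model and a
    per-generator-update log (gen_loss, critic_loss, gp).
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    minibatch_size = cfg.minibatch_size if minibatch_size is None else minibatch_size
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if len(pairs) == 0:
        raise ValueError("cannot train on an empty pair set")
    X_source = np.asarray(X_source, float)
    X_anchor = np.asarray(X_anchor, float)
    if pairs.index_a.max() >= X_source.shape[0] or pairs.index_b.max() >= X_anchor.shape[0]:
        raise IndexError("pair indices exceed the source/anchor matrices")

    gen = nnet.tree_copy(model.gen)
    critic = nnet.tree_copy(model.critic)
    cols = ["step", "gen_loss", "critic_loss", "gp"]
    if epochs == 0:
        out = GanModel(gen, critic, model.d, cfg, model.seed,
                       model.x_mean, model.x_scale)
        return out, pd.DataFrame(columns=cols)

    mu, sc = model.x_mean, model.x_scale
    if cfg.standardize and mu is None:
        used = np.vstack([X_source[np.unique(pairs.index_a)],
                          X_anchor[np.unique(pairs.index_b)]])
        mu = used.mean(axis=0)
        sc = used.std(axis=0)
        sc = np.where(sc < 1e-8, 1.0, sc)
    out = GanModel(gen, critic, model.d, cfg, model.seed, mu, sc)
    lo = out.lo
    Xs1 = out.to_scaled(X_source)
    Xs2 = out.to_scaled(X_anchor)

    rng = np.random.default_rng(seed)
    opt_g = Adam(gen, lr=cfg.learning_rate, betas=cfg.betas)
    opt_c = Adam(critic, lr=cfg.critic_learning_rate or cfg.learning_rate,
                 betas=cfg.betas)
    steps_per_epoch = int(np.ceil(len(pairs) / minibatch_size))
    rows = []
    step = 0
    for _epoch in range(epochs):
        for _ in range(steps_per_epoch):
            c_loss = gp_val = np.nan
            for _ in range(cfg.critic_steps):
                sel = rng.integers(0, len(pairs), size=minibatch_size)
                x1 = Xs1[pairs.index_a[sel]]
                x2 = Xs2[pairs.index_b[sel]]
                fake = np.asarray(_generator_scaled(gen, out, x1, lo))
                eps = rng.random((minibatch_size, 1))
                c_loss, gp_val, grads = _critic_update_grads(out, critic, x2, fake,
                                                             eps, cfg.gp_weight)
                opt_c.step(grads)
            sel = rng.integers(0, len(pairs), size=minibatch_size)
            x1 = Xs1[pairs.index_a[sel]]
            g_loss, grads = _gen_update_grads(out, gen, critic, x1, lo)
            opt_g.step(grads)
            if not (np.isfinite(g_loss) and np.isfinite(c_loss)):
                raise RuntimeError(f"non-finite stage-II loss at generator step {step}: "
                                   f"gen={g_loss}, critic={c_loss}")
            rows.append((step, float(g_loss), float(c_loss), float(gp_val)))
            step += 1
    return out, pd.DataFrame(rows, columns=cols)
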