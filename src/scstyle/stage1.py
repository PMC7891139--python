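"""Stage I: batch-ignorant content representations.

A batch-conditioned autoencoder disentangles a cell's biological content
from its batch of origin. Three networks are trained jointly: an encoder
``E`` (expression -> l-dimensional content code), a noise generator
``G1`` (one-hot batch indicator -> expression-scale noise profile) and a
reconstruction generator ``G2`` (code + indicator -> expression). The
reconstruction is ``G(E(x), b) = f(G1(b) + G2(E(x), b))`` with ``f``
elementwise ReLU, trained under

    L_r = E || G(E(x), b) - x ||^2                      (reconstruction)
    L_c = E || E(G(E(x), b_tilde)) - E(x) ||^2          (content)

where ``b`` is the true one-hot indicator and ``b_tilde`` a uniformly
resampled one. Minimizing ``lambda_c L_c + lambda_r L_r`` pushes the code
to survive a round trip through an arbitrary batch style, i.e. to be
ignorant of the measuring process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd
import autograd.numpy as anp
import numpy as np
import pandas as pd

from . import nnet
from .data import ExpressionSet
from .nnet import Adam, get_activation, init_mlp, mlp_forward, linear, relu


@dataclass
class Stage1Config:
    l: int = 256
    widths: tuple = (1024, 512)
    lambda_c: float = 3.0
    lambda_r: float = 1.0
    learning_rate: float = 5e-4
    betas: tuple = (0.9, 0.999)
    # None: adaptive, targeting ~50 optimizer updates per epoch (capped at
    # 256) so small cohorts still converge within the epoch budget
    minibatch_size: int | None = None
    epochs: int = 150

    def resolve_minibatch(self, n_cells: int) -> int:
        if self.minibatch_size is not None:
            return self.minibatch_size
        return int(min(256, max(8, n_cells // 50)))
    activation: str = "mish"

    def __post_init__(self):
        if min(self.lambda_c, self.lambda_r, self.learning_rate) <= 0:
            raise ValueError("lambda_c, lambda_r and learning_rate must be positive")


@dataclass
class Stage1Model:
    """Parameter container for (E, G1, G2) and the output transform f."""

    encoder: list
    g1: list
    g2: list
    d: int
    n_batches: int
    config: Stage1Config = field(default_factory=Stage1Config)
    batch_names: list | None = None
    seed: int = 0

    @property
    def l(self) -> int:
        return self.config.l

    def _acts(self, n_layers):
        hidden = get_activation(self.config.activation)
        return nnet.standard_activations(n_layers, hidden)

    def params(self):
        return [self.encoder, self.g1, self.g2]

    def with_params(self, params) -> "Stage1Model":
        e, g1, g2 = params
        return Stage1Model(e, g1, g2, self.d, self.n_batches, self.config,
                           self.batch_names, self.seed)


def build_stage1(d: int, n: int, l: int = 256, widths: tuple = (1024, 512),
                 seed: int = 0, config: Stage1Config | None = None) -> Stage1Model:
    """Seeded initialization of the three stage-I networks.

    Shapes: E: d -> w1 -> w2 -> l; G1: n -> w2 -> w1 -> d;
    G2: (n + l) -> w2 -> w1 -> d. The first two layers of every network
    carry the hidden activation (Mish by default), the last is linear.
    """
    if config is None:
        config = Stage1Config(l=l, widths=tuple(widths))
    l, (w1, w2) = config.l, config.widths
    if min(d, n, l, w1, w2) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    encoder = init_mlp([d, w1, w2, l], rng)
    g1 = init_mlp([n, w2, w1, d], rng)
    g2 = init_mlp([n + l, w2, w1, d], rng)
    return Stage1Model(encoder, g1, g2, d=d, n_batches=n, config=config, seed=seed)


# ---------------------------------------------------------------------------
# indicators
# ---------------------------------------------------------------------------

def one_hot(indices: np.ndarray, n: int) -> np.ndarray:
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= n):
        raise ValueError("batch index out of range")
    out = np.zeros((len(indices), n))
    out[np.arange(len(indices)), indices] = 1.0
    return out


def batch_indices(labels: np.ndarray, batch_names: list) -> np.ndarray:
    pos = {b: i for i, b in enumerate(batch_names)}
    return np.array([pos[b] for b in labels], dtype=int)


def sample_random_batch_indicator(n: int, rng: np.random.Generator,
                                  size: int = 1) -> np.ndarray:
    """One-hot indicators with the hot index uniform over the n batches."""
    if n < 1:
        raise ValueError("need at least one batch")
    return one_hot(rng.integers(0, n, size=size), n)


# ---------------------------------------------------------------------------
# forward maps and losses
# ---------------------------------------------------------------------------

def _forward(params, model: Stage1Model, x, b):
    e, g1, g2 = params
    acts_e = model._acts(len(e))
    c = mlp_forward(e, x, acts_e)
    rec = relu(mlp_forward(g1, b, model._acts(len(g1)))
               + mlp_forward(g2, anp.concatenate([c, b], axis=1), model._acts(len(g2))))
    return c, rec


def encode(model: Stage1Model, X: np.ndarray) -> np.ndarray:
    """Content codes for a cells x d matrix (row-wise encoder application)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"expected {model.d} genes, got {X.shape[1]}")
    return np.asarray(mlp_forward(model.encoder, X, model._acts(len(model.encoder))))


def reconstruct(model: Stage1Model, x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """f(G1(b) + G2(E(x), b)) for one cell or a batch of cells."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if x.shape[1] != model.d:
        raise ValueError(f"expected {model.d} genes, got {x.shape[1]}")
    if b.shape[1] != model.n_batches:
        raise ValueError(f"expected {model.n_batches}-long batch indicator")
    _, rec = _forward(model.params(), model, x, b)
    return np.asarray(rec)


def reconstruction_loss(model: Stage1Model, X: np.ndarray, B: np.ndarray) -> float:
    """Minibatch mean of || G(E(x), b) - x ||^2."""
    if len(X) == 0:
        raise ValueError("empty minibatch")
    _, rec = _forward(model.params(), model, np.asarray(X, float), np.asarray(B, float))
    return float(np.mean(np.sum((np.asarray(rec) - X) ** 2, axis=1)))


def content_loss(model: Stage1Model, X: np.ndarray, B_tilde: np.ndarray) -> float:
    """Minibatch mean of || E(G(E(x), b_tilde)) - E(x) ||^2."""
    if len(X) == 0:
        raise ValueError("empty minibatch")
    params = model.params()
    c, fab = _forward(params, model, np.asarray(X, float), np.asarray(B_tilde, float))
    c2 = mlp_forward(params[0], fab, model._acts(len(params[0])))
    return float(np.mean(np.sum((np.asarray(c2) - np.asarray(c)) ** 2, axis=1)))


def _total_loss(params, model, x, b, bt, lam_c, lam_r):
    e = params[0]
    acts_e = model._acts(len(e))
    c, rec = _forward(params, model, x, b)
    l_r = anp.mean(anp.sum((rec - x) ** 2, axis=1))
    _, fab = _forward(params, model, x, bt)
    c2 = mlp_forward(e, fab, acts_e)
    l_c = anp.mean(anp.sum((c2 - c) ** 2, axis=1))
    return lam_c * l_c + lam_r * l_r


_total_loss_vg = autograd.value_and_grad(_total_loss)


def _act_names(model: Stage1Model, n_layers: int) -> list:
    return [model.config.activation] * (n_layers - 1) + ["linear"]


def _stage1_update_grads(model: Stage1Model, params, x, b, bt, lam_c, lam_r):
    """Manual backprop of lam_c*L_c + lam_r*L_r; returns (l_r, l_c, grads).

    The encoder appears three times in the graph (encoding x, inside the
    content target and re-encoding the fabricated cell); all paths
    receive gradients, matching the loss formulas as printed.
    """
    e, g1, g2 = params
    ae = _act_names(model, len(e))
    a1 = _act_names(model, len(g1))
    a2 = _act_names(model, len(g2))
    n = x.shape[0]

    c, cache_e1 = nnet.forward_cache(e, x, ae)
    cb = np.concatenate([c, b], axis=1)
    r1, cache_g1 = nnet.forward_cache(g1, b, a1)
    r2, cache_g2 = nnet.forward_cache(g2, cb, a2)
    pre = r1 + r2
    rec = np.maximum(pre, 0.0)
    diff_r = rec - x
    l_r = float(np.mean(np.sum(diff_r ** 2, axis=1)))

    cbt = np.concatenate([c, bt], axis=1)
    r1t, cache_g1t = nnet.forward_cache(g1, bt, a1)
    r2t, cache_g2t = nnet.forward_cache(g2, cbt, a2)
    pret = r1t + r2t
    fab = np.maximum(pret, 0.0)
    c2, cache_e2 = nnet.forward_cache(e, fab, ae)
    diff_c = c2 - c
    l_c = float(np.mean(np.sum(diff_c ** 2, axis=1)))

    # reconstruction path
    g_rec = lam_r * 2.0 / n * diff_r * (pre > 0)
    grads_g1_a, _ = nnet.backward(g1, cache_g1, a1, g_rec)
    grads_g2_a, gin_cb = nnet.backward(g2, cache_g2, a2, g_rec)
    g_c = gin_cb[:, : c.shape[1]].copy()

    # content path
    g_c2 = lam_c * 2.0 / n * diff_c
    grads_e2, g_fab = nnet.backward(e, cache_e2, ae, g_c2)
    g_pret = g_fab * (pret > 0)
    grads_g1_b, _ = nnet.backward(g1, cache_g1t, a1, g_pret)
    grads_g2_b, gin_cbt = nnet.backward(g2, cache_g2t, a2, g_pret)
    g_c += gin_cbt[:, : c.shape[1]]
    g_c -= g_c2                       # the content target -E(x) term
    grads_e1, _ = nnet.backward(e, cache_e1, ae, g_c)

    grads = [
        nnet.tree_map(np.add, grads_e1, grads_e2),
        nnet.tree_map(np.add, grads_g1_a, grads_g1_b),
        nnet.tree_map(np.add, grads_g2_a, grads_g2_b),
    ]
    return l_r, l_c, grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_stage1(model: Stage1Model, data: ExpressionSet, epochs: int | None = None,
                 minibatch_size: int | None = None, seed: int = 0):
    """Adam-train (E, G1, G2) on all batches jointly.

    Each minibatch contributes both losses: the true indicator ``b``
    drives ``L_r`` and a freshly resampled ``b_tilde`` drives ``L_c``
    (resampling may return the true batch). Returns the trained model and
    a per-epoch loss report (columns: epoch, recon_loss, content_loss,
    total_loss; epoch means over minibatches).
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    if minibatch_size is None:
        minibatch_size = cfg.resolve_minibatch(data.n_cells)
    if epochs < 0:
        raise ValueError("epochs must be >= 0")

    batch_names = data.batch_names
    if len(batch_names) != model.n_batches:
        raise ValueError(f"model built for {model.n_batches} batches, data has {len(batch_names)}")
    X = np.asarray(data.matrix, dtype=float)
    if X.shape[1] != model.d:
        raise ValueError(f"model expects {model.d} genes, data has {X.shape[1]}")
    B = one_hot(batch_indices(data.batch_labels, batch_names), model.n_batches)

    params = nnet.tree_copy(model.params())
    out = model.with_params(params)
    out.batch_names = list(batch_names)
    if epochs == 0:
        return out, pd.DataFrame(columns=["epoch", "recon_loss", "content_loss", "total_loss"])

    rng = np.random.default_rng(seed)
    opt = Adam(params, lr=cfg.learning_rate, betas=cfg.betas)
    n = X.shape[0]
    rows = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        lr_vals, lc_vals = [], []
        for start in range(0, n, minibatch_size):
            idx = order[start:start + minibatch_size]
            xb, bb = X[idx], B[idx]
            bt = sample_random_batch_indicator(model.n_batches, rng, size=len(idx))
            l_r_val, l_c_val, grads = _stage1_update_grads(
                out, params, xb, bb, bt, cfg.lambda_c, cfg.lambda_r)
            lr_vals.append(l_r_val)
            lc_vals.append(l_c_val)
            opt.step(grads)
        l_r, l_c = float(np.mean(lr_vals)), float(np.mean(lc_vals))
        total = cfg.lambda_c * l_c + cfg.lambda_r * l_r
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite stage-I loss at epoch {epoch}: "
                               f"L_r={l_r}, L_c={l_c}")
        rows.append((epoch, l_r, l_c, total))
    report = pd.DataFrame(rows, columns=["epoch", "recon_loss", "content_loss", "total_loss"])
    return out, report
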