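"""Probe classifiers and gene-importance attribution.

Two probes interrogate the trained correction model:

* a **cell-type probe** — a three-layer classifier on the *frozen*
  stage-I encoder's content codes, trained against external cell-type
  labels. Attributing its predictions back through the encoder to input
  genes scores each gene's importance for building the representations.
* a **batch probe** — the same architecture on raw (uncorrected)
  expression against batch-origin labels; its gene attributions score
  importance for carrying (hence removing) batch effects.

Attribution backends are pluggable. The default, ``integrated_gradients``,
integrates the input gradient of the predicted-class logit along the
segment from the background-mean baseline to the cell (Gauss-Legendre
quadrature), so attributions satisfy the additive completeness identity
sum_g a_g = f(x) - f(baseline) up to quadrature error.
``expected_gradients`` is the stochastic variant that samples baselines
from the background set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd
import autograd.numpy as anp
import numpy as np
import pandas as pd

from . import nnet
from .nnet import Adam, init_mlp, mlp_forward, standard_activations
from .stage1 import Stage1Model, encode


@dataclass
class ProbeConfig:
    widths: tuple = (256, 64)
    learning_rate: float = 1e-3
    betas: tuple = (0.9, 0.999)
    minibatch_size: int = 128
    epochs: int = 300
    holdout_fraction: float = 0.2
    min_class_size: int = 5
    # heavy input dropout (feature bagging) and decoupled weight decay
    # spread reliance across redundant informative features — a lone
    # perfect predictor would otherwise absorb all attribution credit;
    # inputs are z-scored so the decay acts uniformly across genes
    input_dropout: float = 0.7
    weight_decay: float = 0.03
    standardize_input: bool = True
    # for the encoder-chained probe: dropout applied to genes *before*
    # the frozen encoder, so gene-level attribution credit also spreads
    gene_dropout: float = 0.3


@dataclass
class ProbeClassifier:
    """A trained three-layer softmax probe, optionally behind an encoder."""

    params: list
    classes: np.ndarray
    in_dim: int
    holdout_accuracy: float
    encoder: Stage1Model | None = None   # set for the cell-type probe chain
    config: ProbeConfig = field(default_factory=ProbeConfig)
    x_mean: np.ndarray | None = None     # probe-input standardization
    x_scale: np.ndarray | None = None

    def _standardize(self, X):
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_scale

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if self.encoder is not None:
            X = encode(self.encoder, X)
        return np.asarray(mlp_forward(self.params, self._standardize(X),
                                      standard_activations(len(self.params))))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.logits(X), axis=1)]


def _cross_entropy(params, X, Y):
    logits = mlp_forward(params, X, standard_activations(len(params)))
    logits = logits - anp.max(logits, axis=1, keepdims=True)
    logz = anp.log(anp.sum(anp.exp(logits), axis=1))
    return anp.mean(logz - anp.sum(logits * Y, axis=1))


_ce_vg = autograd.value_and_grad(_cross_entropy)


def _train_probe(X: np.ndarray, labels: np.ndarray, seed: int,
                 config: ProbeConfig, encoder: Stage1Model | None = None):
    """Train the softmax probe; with ``encoder`` the raw gene matrix is
    encoded per minibatch (after gene-level dropout) through the frozen
    encoder."""
    X_raw = X
    if encoder is not None:
        X = encode(encoder, X_raw)
    mu = sc = None
    if config.standardize_input:
        mu = X.mean(axis=0)
        sc = X.std(axis=0)
        sc = np.where(sc < 1e-8, 1.0, sc)
        X = (X - mu) / sc
    classes, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y)
    small = classes[counts < config.min_class_size]
    if len(small):
        warnings.warn(f"classes with < {config.min_class_size} cells excluded: {list(small)}")
        keep = ~np.isin(labels, small)
        X, labels, X_raw = X[keep], labels[keep], X_raw[keep]
        classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("probe training needs at least two usable classes")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    order = rng.permutation(n)
    n_test = max(1, int(round(config.holdout_fraction * n)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    Y = np.zeros((n, len(classes)))
    Y[np.arange(n), y] = 1.0

    w1, w2 = config.widths
    params = init_mlp([X.shape[1], w1, w2, len(classes)], rng)
    opt = Adam(params, lr=config.learning_rate, betas=config.betas)
    for _epoch in range(config.epochs):
        perm = rng.permutation(len(train_idx))
        for start in range(0, len(train_idx), config.minibatch_size):
            idx = train_idx[perm[start:start + config.minibatch_size]]
            if encoder is not None and config.gene_dropout > 0:
                gmask = rng.random(X_raw[idx].shape) >= config.gene_dropout
                xb = encode(encoder, X_raw[idx] * gmask / (1.0 - config.gene_dropout))
                if mu is not None:
                    xb = (xb - mu) / sc
            else:
                xb = X[idx]
            if config.input_dropout > 0:
                keep = rng.random(xb.shape) >= config.input_dropout
                xb = xb * keep / (1.0 - config.input_dropout)
            _, grads = _ce_vg(params, xb, Y[idx])
            opt.step(grads)
            if config.weight_decay > 0:
                for W, _b in params:
                    W *= 1.0 - config.learning_rate * config.weight_decay
    logits = mlp_forward(params, X[test_idx], standard_activations(len(params)))
    acc = float(np.mean(np.argmax(logits, axis=1) == y[test_idx]))
    return params, classes, acc, mu, sc


def train_celltype_probe(encoder_model: Stage1Model, X: np.ndarray,
                         celltypes: np.ndarray, seed: int = 0,
                         config: ProbeConfig | None = None) -> ProbeClassifier:
    """Cell-type probe on frozen encoder codes.

    The encoder's parameters are read, never written; the returned probe
    keeps a reference so gene attributions can be composed through it.
    """
    # moderate code-level dropout: the gene-level dropout upstream of the
    # frozen encoder does most of the credit spreading here
    config = config or ProbeConfig(input_dropout=0.5)
    params, classes, acc, mu, sc = _train_probe(np.asarray(X, float),
                                                np.asarray(celltypes), seed,
                                                config, encoder=encoder_model)
    return ProbeClassifier(params, classes, in_dim=encoder_model.d,
                           holdout_accuracy=acc, encoder=encoder_model,
                           config=config, x_mean=mu, x_scale=sc)


def train_batch_probe(X: np.ndarray, batches: np.ndarray, seed: int = 0,
                      config: ProbeConfig | None = None) -> ProbeClassifier:
    """Batch-origin probe on (uncorrected) expression."""
    config = config or ProbeConfig()
    X = np.asarray(X, float)
    params, classes, acc, mu, sc = _train_probe(X, np.asarray(batches), seed, config)
    return ProbeClassifier(params, classes, in_dim=X.shape[1],
                           holdout_accuracy=acc, encoder=None, config=config,
                           x_mean=mu, x_scale=sc)


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Signed per-(cell, gene) attribution scores for one probe."""

    scores: np.ndarray                 # cells x genes
    gene_ids: np.ndarray
    cell_index: np.ndarray
    predicted_class: np.ndarray
    method: str

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.gene_ids)
        df.insert(0, "cell", self.cell_index)
        return df.melt(id_vars="cell", var_name="gene", value_name="score")

    def aggregate(self, groups: np.ndarray, absolute: bool = True) -> pd.DataFrame:
        """Per-gene median (|score| by default) within each group."""
        groups = np.asarray(groups)
        S = np.abs(self.scores) if absolute else self.scores
        rows = {}
        for g in pd.unique(groups):
            rows[g] = np.median(S[groups == g], axis=0)
        return pd.DataFrame(rows, index=self.gene_ids)

    def top_genes(self, groups: np.ndarray | None = None, n: int = 10) -> dict:
        """Top-n genes by group median |score| (one global group if None)."""
        if groups is None:
            groups = np.zeros(len(self.scores), dtype=int)
        agg = self.aggregate(groups, absolute=True)
        return {g: list(agg[g].sort_values(ascending=False).index[:n]) for g in agg.columns}


def _chain_logit_fn(probe: ProbeClassifier):
    probe_acts = standard_activations(len(probe.params))
    mu, sc = probe.x_mean, probe.x_scale

    def std(v):
        return v if mu is None else (v - mu) / sc

    if probe.encoder is None:
        def f(x, cls_idx):
            logits = mlp_forward(probe.params, std(x), probe_acts)
            return logits[anp.arange(x.shape[0]), cls_idx]
    else:
        enc = probe.encoder

        def f(x, cls_idx):
            c = mlp_forward(enc.encoder, x, enc._acts(len(enc.encoder)))
            logits = mlp_forward(probe.params, std(c), probe_acts)
            return logits[anp.arange(x.shape[0]), cls_idx]
    return f


ATTRIBUTION_METHODS = ("integrated_gradients", "expected_gradients")


def gene_importance(probe: ProbeClassifier, X: np.ndarray,
                    background: np.ndarray, method: str = "integrated_gradients",
                    gene_ids: np.ndarray | None = None, n_samples: int = 64,
                    seed: int = 0) -> ImportanceTable:
    """Attribute each cell's predicted-class logit to input genes.

    For the cell-type probe the gradient flows through the frozen
    encoder, so scores land on genes, not code dimensions. ``background``
    is a sample of cells defining the baseline; ``n_samples`` is the
    quadrature order (integrated gradients) or the number of
    (baseline, path-position) draws (expected gradients).
    """
    if method not in ATTRIBUTION_METHODS:
        raise ValueError(f"unknown attribution backend {method!r}; "
                         f"available: {ATTRIBUTION_METHODS}")
    X = np.atleast_2d(np.asarray(X, float))
    background = np.atleast_2d(np.asarray(background, float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    f = _chain_logit_fn(probe)
    cls_idx = np.argmax(probe.logits(X), axis=1)
    grad_f = autograd.grad(lambda z: anp.sum(f(z, cls_idx)))

    if method == "integrated_gradients":
        baseline = background.mean(axis=0, keepdims=True)
        diff = X - baseline
        nodes, weights = np.polynomial.legendre.leggauss(n_samples)
        alphas = 0.5 * (nodes + 1.0)          # map [-1, 1] -> [0, 1]
        weights = 0.5 * weights
        total = np.zeros_like(X)
        for a, w in zip(alphas, weights):
            total += w * np.asarray(grad_f(baseline + a * diff))
        scores = diff * total
    else:
        rng = np.random.default_rng(seed)
        total = np.zeros_like(X)
        for _ in range(n_samples):
            b = background[rng.integers(0, background.shape[0], size=X.shape[0])]
            a = rng.random((X.shape[0], 1))
            total += (X - b) * np.asarray(grad_f(b + a * (X - b)))
        scores = total / n_samples

    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    return ImportanceTable(scores=scores, gene_ids=np.asarray(gene_ids, object),
                           cell_index=np.arange(X.shape[0]),
                           predicted_class=probe.classes[cls_idx], method=method)
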