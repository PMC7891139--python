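"""Minimal feed-forward network toolkit.

All five networks of the correction framework are small multilayer
perceptrons; their parameters are nested ``[ [W, b], ... ]`` lists of numpy
arrays and gradients are obtained with :mod:`autograd`, which also yields
the exact second-order derivatives required by the gradient penalty of the
Wasserstein critic. Every stochastic choice is driven by an explicit
``numpy.random.Generator`` so that training is bitwise reproducible.
"""

from __future__ import annotations

from typing import Callable, Sequence

import autograd.numpy as anp
import numpy as np

Params = list  # nested [ [W, b], ... ]
Activation = Callable


def mish(x):
    """Self-regularized non-monotonic activation x * tanh(softplus(x))."""
    return x * anp.tanh(anp.logaddexp(0.0, x))


def relu(x):
    return anp.maximum(x, 0.0)


def linear(x):
    return x


_ACTIVATIONS = {"mish": mish, "relu": relu, "linear": linear}


def get_activation(name_or_fn) -> Activation:
    if callable(name_or_fn):
        return name_or_fn
    try:
        return _ACTIVATIONS[name_or_fn]
    except KeyError:
        raise ValueError(
            f"unknown activation {name_or_fn!r}; available: {sorted(_ACTIVATIONS)}"
        ) from None


def init_mlp(dims: Sequence[int], rng: np.random.Generator) -> Params:
    """He-style initialization of an MLP with the given layer widths."""
    if any(d < 1 for d in dims):
        raise ValueError(f"all layer widths must be >= 1, got {tuple(dims)}")
    params = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        W = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        params.append([W, np.zeros(fan_out)])
    return params


def mlp_forward(params: Params, x, activations: Sequence[Activation]):
    """Apply an MLP; ``activations[i]`` follows affine layer ``i``.

    ``len(activations)`` must equal ``len(params)``; use :func:`linear`
    for layers without a non-linearity.
    """
    h = x
    for (W, b), act in zip(params, activations, strict=True):
        h = act(h @ W + b)
    return h


def standard_activations(n_layers: int, hidden: Activation = mish) -> list:
    """Hidden layers activated, final layer linear (the default layout)."""
    return [hidden] * (n_layers - 1) + [linear]


def tree_map(fn, *trees):
    """Map ``fn`` over parallel nested lists of arrays."""
    if isinstance(trees[0], (list, tuple)):
        return [tree_map(fn, *sub) for sub in zip(*trees)]
    return fn(*trees)


def tree_copy(tree):
    return tree_map(np.array, tree)


def tree_equal(a, b) -> bool:
    flags: list[bool] = []
    tree_map(lambda x, y: flags.append(np.array_equal(x, y)), a, b)
    return all(flags)


def tree_finite(tree) -> bool:
    flags: list[bool] = []
    tree_map(lambda x: flags.append(bool(np.all(np.isfinite(x)))), tree)
    return all(flags)


class Adam:
    """Adam optimizer over a nested parameter list (in-place updates)."""

    def __init__(self, params: Params, lr: float, betas=(0.5, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = tree_map(np.zeros_like, params)
        self.v = tree_map(np.zeros_like, params)

    def step(self, grads: Params) -> None:
        self.t += 1
        b1, b2, lr, eps, t = self.b1, self.b2, self.lr, self.eps, self.t

        def upd(p, g, m, v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
            return p

        tree_map(upd, self.params, grads, self.m, self.v)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one integer seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# hand-rolled backpropagation
#
# Training loops use explicit numpy backprop (an order of magnitude faster
# than tracing a fresh autograd graph per minibatch for networks this
# small); autograd remains the independent oracle for these gradients in
# the test suite and the engine for input-space attribution.
# ---------------------------------------------------------------------------

def _mish_fwd(z):
    # tanh(softplus(z)) and sigmoid(z) from one exp:
    #   E = e^z, tanh(log(1+E)) = ((1+E)^2 - 1) / ((1+E)^2 + 1)
    E = np.exp(np.minimum(z, 30.0))
    P = (1.0 + E) ** 2
    t = 1.0 - 2.0 / (P + 1.0)
    sig = E / (1.0 + E)
    return z * t, (t, sig)


def _mish_d1(z, aux):
    t, sig = aux
    return t + z * sig * (1.0 - t * t)


def _mish_d2(z, aux):
    t, sig = aux
    return sig * (1.0 - t * t) * (2.0 + z * (1.0 - sig - 2.0 * t * sig))


_NP_ACTS = {
    "mish": (_mish_fwd, _mish_d1, _mish_d2),
    "relu": (lambda z: (np.maximum(z, 0.0), None),
             lambda z, aux: (z > 0).astype(float),
             lambda z, aux: np.zeros_like(z)),
    "linear": (lambda z: (z, None),
               lambda z, aux: np.ones_like(z),
               lambda z, aux: np.zeros_like(z)),
}


def act_name(act: Activation) -> str:
    for name, fn in _ACTIVATIONS.items():
        if fn is act:
            return name
    raise ValueError(f"activation {act!r} has no numpy derivative table")


def forward_cache(params: Params, x: np.ndarray, act_names: Sequence[str]):
    """Forward pass caching per-layer inputs, pre-activations and the
    activation's reusable intermediates."""
    h = x
    cache = []
    for (W, b), name in zip(params, act_names, strict=True):
        z = h @ W + b
        out, aux = _NP_ACTS[name][0](z)
        cache.append((h, z, aux))
        h = out
    return h, cache


def backward(params: Params, cache, act_names: Sequence[str], gout: np.ndarray):
    """VJP through an MLP: returns (param_grads, input_grad)."""
    g = gout
    grads = [None] * len(params)
    for i in range(len(params) - 1, -1, -1):
        h_in, z, aux = cache[i]
        g = g * _NP_ACTS[act_names[i]][1](z, aux)
        grads[i] = [h_in.T @ g, g.sum(axis=0)]
        g = g @ params[i][0].T
    return grads, g


def input_gradient_2h(params: Params, x: np.ndarray, act_names: Sequence[str]):
    """grad_x of a scalar-output 2-hidden-layer MLP, per sample.

    Returns (g, aux) where aux caches the quantities the gradient-penalty
    backward pass (:func:`gp_param_grads_2h`) reuses.
    """
    (W1, b1), (W2, b2), (W3, b3) = params
    f1, df1, _ = _NP_ACTS[act_names[0]]
    f2, df2, _ = _NP_ACTS[act_names[1]]
    if act_names[2] != "linear":
        raise ValueError("scalar critic output layer must be linear")
    z1 = x @ W1 + b1
    h1, aux1 = f1(z1)
    z2 = h1 @ W2 + b2
    _h2, aux2 = f2(z2)
    a1 = df1(z1, aux1)
    a2 = df2(z2, aux2)
    w = W3[:, 0]
    s2 = a2 * w                      # (n, h2)
    u = s2 @ W2.T                    # (n, h1)
    v = a1 * u                       # (n, h1)
    g = v @ W1.T                     # (n, d)
    return g, (z1, h1, z2, a1, a2, u, v, s2, aux1, aux2)


def gp_param_grads_2h(params: Params, x: np.ndarray, act_names: Sequence[str],
                      r: np.ndarray, aux) -> Params:
    """Parameter gradient of sum_i r_i . grad_x D(x_i) for a 2-hidden-layer
    scalar critic (the second-order term of the gradient penalty); ``r``
    carries the outer derivative d penalty / d grad_x D.
    """
    (W1, b1), (W2, b2), (W3, b3) = params
    _, _, d2f1 = _NP_ACTS[act_names[0]]
    _, _, d2f2 = _NP_ACTS[act_names[1]]
    z1, h1, z2, a1, a2, u, v, s2, aux1, aux2 = aux
    w = W3[:, 0]

    P = r @ W1                       # (n, h1)
    gW1 = r.T @ v                    # (d, h1) explicit term
    q1 = P * u * d2f1(z1, aux1)      # (n, h1) through a1
    gW1 += x.T @ q1
    gb1 = q1.sum(axis=0)
    T = a1 * P                       # (n, h1) dS/du
    gW2 = T.T @ s2                   # (h1, h2) explicit term
    Wt = T @ W2                      # (n, h2)
    q2 = Wt * w * d2f2(z2, aux2)     # (n, h2) through a2
    gW2 += h1.T @ q2
    gb2 = q2.sum(axis=0)
    q1b = (q2 @ W2.T) * a1           # (n, h1) through h1 in z2
    gW1 += x.T @ q1b
    gb1 = gb1 + q1b.sum(axis=0)
    gw3 = (Wt * a2).sum(axis=0)      # (h2,) through w
    return [[gW1, gb1], [gW2, gb2], [gw3[:, None], np.zeros_like(b3)]]
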