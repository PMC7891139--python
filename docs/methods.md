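# Methods

## Problem setting

Single-cell RNA-seq experiments run on different days, platforms or
protocols carry systematic technical differences ("batch effects") that
confound biological variation. Integrating such datasets requires mixing
the cell types the batches share while *not* forcing together populations
that genuinely occur in only one batch. `scstyle` treats correction as
paired style transfer: one batch is chosen as the **anchor** and left
untouched; every other batch is transformed, gene by gene and cell by
cell, into the anchor's "measurement style".

## Stage I — batch-ignorant content codes

The measured expression vector `x` (log-TPM scale, HVG-restricted) is
modelled as a function of biological content and measuring process. Three
feed-forward networks are trained jointly:

* encoder `E: x -> c` (`d -> w1 -> w2 -> l`),
* noise generator `G1: b -> noise profile` (`n -> w2 -> w1 -> d`),
* reconstruction generator `G2: (c, b) -> profile` (`(n+l) -> w2 -> w1 -> d`),

where `b` is the one-hot batch indicator of length `n`. The reconstruction
is `G(E(x), b) = f(G1(b) + G2(E(x), b))` with `f = ReLU`, and the losses

    L_r = E ||G(E(x), b) - x||^2
    L_c = E ||E(G(E(x), b~)) - E(x)||^2

are combined as `lambda_c L_c + lambda_r L_r` with `lambda_c = 3`,
`lambda_r = 1`. `b~` is a fresh uniform one-hot draw per cell per
minibatch (it may equal the true batch; the formula imposes no
exclusion). No stop-gradient is placed on the content target `E(x)`:
every appearance of the encoder receives gradients, which reads the loss
exactly as written. Hidden layers use the Mish activation, final layers
are linear. Optimization is Adam with learning rate 5e-4 and betas
(0.9, 0.999) — stage I is an ordinary autoencoder, not an adversarial
game, and the conventional first moment converges markedly faster at a
fixed epoch budget; this matters because the quality of everything
downstream (pair purity in particular, see below) tracks stage-I
convergence. The minibatch size defaults to an adaptive rule targeting
about 50 optimizer updates per epoch, capped at 256, for the same reason.

## Stage II — adversarial correction on rwMNN pairs

### Pairing

Pairs of "biologically similar" cells across batches supervise the
transfer. In content-code space, an **MNN pair** is a pair of cells, one
per batch, each inside the other's `k` nearest cross-batch neighbours.
Because raw MNN pairs concentrate in the densest part of the shared
types, each seed pair is extended by `m` chained random-walk steps: at
each step one uniform draw from the `k1` within-batch neighbours of the
current batch-A member, and independently of the batch-B member, yields
the next pair (and the walk state). Defaults follow the
subsample-formula: at most `s = 3000` cells per batch are used for
pairing, `k1 = max(1, s_eff/100)` with `s_eff = min(s, batch size)`,
`k = max(1, k1/2)`, `m = 50`. Pre-deduplication the extended list has
exactly `M (m+1)` entries; duplicates are kept by default (they weight
dense regions). Exhaustive nearest-neighbour search (stable,
index-ordered tie-breaking) is used up to 2048 pooled cells; above that a
pynndescent approximate index takes over.

### Adversarial objective

The generator is a residual shortcut `G'(x) = f(F(x) + x)` with `F` an
autoencoder-shaped network `d -> w1 -> w2 -> l -> w2 -> w1 -> d` (Mish
hidden layers; the bottleneck and the output layer are linear — the
output layer must be unbounded below or the generator could never remove
a positive batch shift). `F`'s output layer is zero-initialized, so the
untrained generator is exactly the identity on non-negative input and
only learns critic-driven deviations; this protects cells outside the
training pairs (in particular batch-specific populations) from arbitrary
extrapolation. The critic `D'` is `d -> w3 -> w3 -> 1`, and training uses
the WGAN-GP objective

    min_G' max_D'  E D'(x2) - E D'(G'(x1)) - gp_weight E (||grad D'(x^)|| - 1)^2

with interpolates `x^` uniform on segments between paired real and
generated samples, `gp_weight = 10`. Only cells appearing in rwMNN pairs
are ever used in training — pairs (not cells) are the sampling unit,
drawn uniformly with replacement; the source member feeds `G'`, the
anchor member is the critic's real sample. One epoch is
`ceil(|pairs| / minibatch)` generator updates (minibatch 512), each
preceded by `critic_steps = 2` critic updates. Learning rates: generator
2e-4; critic 4e-4 (a mild two-timescale split — the critic must track a
moving target and under-trained critics were the dominant failure mode in
our benchmarks; both values configurable).

### Conditioning

Stage-II training runs in gene-standardized coordinates
`x~ = (x - mu)/sigma`, with `mu`, `sigma` estimated from the cells the
pairs reference. This is an exact reparametrization of the same model
family (`G'(x) = relu(F(x) + x)` with `F(x) = sigma * F~(x~)`; the ReLU
floor maps to `max(., -mu/sigma)` in scaled space), but the critic's
unit-Lipschitz ball — and hence the transport metric — then weighs every
gene equally instead of being dominated by high-expression genes. On the
benchmark design this roughly halves the residual cross-batch offset at a
fixed epoch budget. The fitted `mu`/`sigma` are stored on the model, so
`transform` is self-contained; a freshly built model has identity
scaling, under which all formulas reduce to their classic form.

### Multi-batch orchestration

The batch with the largest total gene-wise variance (sum of per-gene
variances of the HVG log-TPM matrix) is the anchor; remaining batches are
processed in decreasing variance order (ties broken lexicographically;
both choices can be overridden). Stage I is trained once on all batches
jointly. Each non-anchor batch is paired against the *grown* anchor pool
(anchor cells plus previously corrected cells, reusing their original
stage-I codes), a fresh GAN is trained, and the whole batch — paired or
not — is transformed and appended to the pool. Anchor cells pass through
bit-identical. If a batch yields no seed pairs it is appended uncorrected
with a provenance flag (a conservative fallback; geometrically the
globally nearest cross-batch pair is always mutual, so this cannot occur
with non-empty batches — the path exists for defensive completeness).
Whole-transcriptome mode partitions the shared gene list into `n_chunks`
(default 10) seeded near-equal chunks, reuses the code-space pairs across
chunks, and trains one independent GAN per chunk; columns are reassembled
in the original gene order.

Determinism: a single seed fans out through `numpy.random.SeedSequence`
keyed by role and round, and input batches are canonicalized by batch id,
so results are bitwise reproducible and independent of input order.

## Evaluation metric

Every cell is labelled by two successive local classifiers on any
per-cell coordinate matrix (corrected expression by default):

* **positive** — at least 50% of its `k = min(100, type size)` nearest
  neighbours (self excluded) share its cell type;
* **true positive** — a positive cell whose neighbourhood batch counts
  `k_i` all fall inside the three-sigma binomial band
  `[max(0, k p_i - 3 sqrt(k p_i (1-p_i))), k p_i + 3 sqrt(k p_i (1-p_i))]`
  around the type's global batch proportions `p_i`.

Batch-specific types have degenerate bands (`p_i` 0 or 1) and therefore
are not penalized for being unmixed. Interval endpoints stay real-valued.
Cell types with fewer than two cells are excluded from the denominators
and tallied separately. The summary is the pair (proportion positive,
proportion true positive).

## Gene importance

Two three-layer softmax probes (widths 256/64, cross-entropy, 80/20
split) interrogate the model: a cell-type probe on the *frozen* encoder's
codes and a batch-origin probe on uncorrected expression. Probe inputs
are z-scored and training uses heavy input dropout (0.7, effectively
feature bagging) plus decoupled weight decay (0.03): with redundant
informative genes an unregularized probe lets a single perfect predictor
absorb all attribution, and the ridge-like regularization spreads credit
across every informative feature — without it, planted diagnostic genes
with large raw effect sizes can receive near-zero attribution. The
cell-type probe additionally applies gene-level dropout (0.3) *upstream*
of the frozen encoder during training, spreading gene-level credit
through the chain (the code-level dropout is relaxed to 0.5 there). Attribution backends are pluggable:
`integrated_gradients` (default) integrates the predicted-class logit's
input gradient from the background-mean baseline along the straight path
using 64-node Gauss-Legendre quadrature, so the completeness identity
`sum_g a_g = f(x) - f(baseline)` holds to quadrature accuracy;
`expected_gradients` is the stochastic variant sampling baselines from
the background set. For the cell-type probe the gradient flows through
the frozen encoder so scores land on genes. Reported rankings use
per-gene medians of |score| within groups.

## Synthetic data

The simulator draws per-type mean profiles as a shared lognormal gene
baseline (log-mean 1, sigma 1) modulated by per-type lognormal jitter
(sigma 0.6) and a 4-fold boost on 5 planted marker genes per type; counts
are gamma-Poisson (negative binomial, dispersion 0.3). Batch effects are
gene-wise additive shifts on the log-scale mean (sigma 0.8 in the `small`
design, with 3 planted diagnostic genes at +/-2.5), gene-wise lognormal
multiplicative factors (sigma 0.3), and optional extra dropout (used in
the `medium` design only). The named designs: `tiny` (2 x 80 cells, 60
genes, 3 shared types), `small` (2 x 400 cells, 200 genes, 2 shared + 1
batch-specific type per batch), `medium` (3 x 1000 cells, 2000 genes, 6
types, mixed presence, dropout). Every simulated cell carries its true
type, batch and effect vectors.

What the simulator does *not* emulate: UMI/read-level artifacts,
gene-length bias, ambient RNA, doublets, and realistic gene-gene
correlation structure (genes are conditionally independent given type and
batch). Passing benchmarks on it demonstrates that the pipeline removes
gene-wise multiplicative/additive distortions while preserving discrete
population structure — not that it handles every failure mode of real
protocols.

## Known limitations

* **Forced pairing of batch-specific types.** When each of two batches
  carries a private population, mutual-nearest-neighbour pairing links
  the two orphans "by elimination": each is the other's nearest
  cross-batch cluster. A handful of such cross-type seed pairs appears in
  every simulation seed, and the random walk amplifies them
  proportionally. A smooth generator trained on even a few such pairs
  maps the whole private population toward its false partner. This
  creates a measurable trade-off between mixing strength for shared types
  and survival of batch-specific structure; the default optimizer
  settings sit at the knee of that frontier (controlled experiments with
  ground-truth-filtered pairs confirm pair impurity, not adversarial
  optimization, is the binding constraint). Stronger stage-I convergence
  raises pair purity and softens, but does not eliminate, the effect.
* The benchmark (reduced widths, 100 epochs, two batches of 400 cells)
  was sized for a single CPU; the production defaults (widths 1024/512,
  l = 256, 150 epochs) follow the reference architecture and are intended
  for GPUs or longer CPU runs.
* The evaluation metric depends on the coordinate space supplied; the
  package evaluates corrected expression directly, which is stricter than
  evaluating a compacted 2-D embedding of it.
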