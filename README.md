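# scstyle

Batch-effect removal for single-cell RNA-seq by **adversarial paired
style transfer**, with the matching single-cell-level evaluation metric
and probe-based gene-importance scores.

Integrating scRNA-seq datasets from different platforms or runs requires
removing technical variation while keeping biological variation — in
particular, mixing the cell types the batches share without force-mixing
populations that genuinely exist in only one batch. `scstyle` implements
a two-stage unsupervised framework:

1. **Stage I — batch-ignorant content codes.** A batch-conditioned
   autoencoder (encoder `E`, noise generator `G1`, reconstruction
   generator `G2`) reconstructs each cell as
   `G(E(x), b) = ReLU(G1(b) + G2(E(x), b))` from its expression vector
   `x` and one-hot batch indicator `b`, under a reconstruction loss
   `L_r = E‖G(E(x), b) − x‖²` and a content loss
   `L_c = E‖E(G(E(x), b̃)) − E(x)‖²` (with `b̃` a random indicator),
   weighted `λ_c L_c + λ_r L_r` (defaults 3 and 1). The code
   `c = E(x)` captures what a cell *is*, independent of how it was
   measured.
2. **Stage II — adversarial correction.** Mutual-nearest-neighbour (MNN)
   pairs found in code space are expanded by within-batch random walks
   (**rwMNN** pairs, `k1`-neighbour steps, `m = 50` iterations) to cover
   the full distributions of the shared types. A residual generator
   `G'(x) = ReLU(F(x) + x)` is trained against a critic `D'` under the
   WGAN-GP objective, *only* on those pairs, to transform source-batch
   cells into the style of an anchor batch (the batch with the largest
   total variance, left untouched). All cells of the batch are then
   transformed; with more than two batches, corrected batches join the
   anchor pool incrementally.

Also included: the **positive / true-positive** mixing metric (a cell is
*positive* if ≥ 50% of its `k = min(100, type size)` nearest neighbours
share its type, and *true positive* if additionally its neighbourhood
batch composition lies within three binomial standard deviations of the
type's global batch composition, for every batch), probe classifiers with
integrated-gradients gene attribution, and a seeded negative-binomial
multi-batch simulator with planted marker and batch-diagnostic genes.

## Worked example

```python
import numpy as np
from scstyle import (default_benchmark_design, simulate, qc_filter,
                     log_tpm_transform, integrate_all, evaluate_mixing,
                     summarize)
from scstyle.benchmark import benchmark_config

# two batches x 400 cells, 200 genes; types A, B shared, C only in
# batch0, D only in batch1; gene-wise additive+multiplicative batch effect
counts, truth = simulate(default_benchmark_design("small", seed=1))
logged = log_tpm_transform(qc_filter(counts))

before = evaluate_mixing(logged.matrix, logged.celltype_labels,
                         logged.batch_labels)
print("before:", summarize(before))

result = integrate_all(list(logged.split_batches().values()),
                       benchmark_config(), seed=1)
after = evaluate_mixing(result.corrected.matrix,
                        result.corrected.celltype_labels,
                        result.corrected.batch_labels)
print("anchor:", result.plan.anchor_batch_id)
print("after:", summarize(after))
```

prints (reduced benchmark widths, 100 epochs per stage, one CPU):

```
before: (1.0, 0.1675)
anchor: batch0
after: (0.94875, 0.5)
```

Before correction every cell sits in a pure same-type neighbourhood
(positive proportion 1.0) but only the batch-specific cells pass the
batch-composition test (true-positive proportion 0.17, below their 0.25
share of the data): the shared types are completely unmixed. After
correction the
true-positive proportion rises to 0.50 — the corrected batch-1 cells now
interleave with their anchor counterparts — while the positive
proportion stays near 1, i.e. cell-type structure (including the
batch-specific populations, which the anchor passthrough and the
identity-initialised residual generator protect) survives the transfer.

A command-line interface mirrors the library:
`scstyle simulate`, `scstyle integrate`, `scstyle evaluate`.

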