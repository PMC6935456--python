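# consonet

Selecting differentially expressed biomarker genes from **multiple
gene-aligned omics studies** with a consolidation-layer neural network and
a lasso-penalized logistic output.

Bulk or single-platform differential-expression tools analyze one study at
a time; combining studies (mRNA, methylation, CNV measured on the same
cohort, or several expression cohorts measuring the same genes) increases
power and yields more reproducible markers. `consonet` implements a small
feedforward network built for exactly this vertical-integration setting,
together with a synthetic multi-study generator and a
sensitivity/specificity benchmarking harness. It is aimed at
computational biologists who want a selection method that treats each
gene's evidence across D studies as one unit.

## Model

Each of the K genes owns one hidden node per study. For sample *i*,
gene *k*, study *m* with input features *x* and weights *v*:

    a_ikm = Σ_p v_kmp · x_ikmp            (pre-activation)
    O_ikm = max(a_ikm, 0)                 (ReLU)
    C_ik  = Σ_m w_km · O_ikm / ‖w_k‖₂    (consolidation node, one per gene)
    ŷ_i   = β₀ + Σ_k β_k · C_ik
    f_i   = 1 / (1 + e^(−ŷ_i))           (class probability)

Training minimizes the penalized cross-entropy

    R^λ = −(1/N) Σ_i [y_i log f_i + (1−y_i) log(1−f_i)] + λ Σ_k |β_k|

by full-batch backpropagation: a damped Newton-style sweep on β (the
lasso term's curvature at zero is defined through the smooth sign
z(β) = 2·sigmoid(β/s) − 1, s = 10⁻³), and gradient steps on β₀, w and v.
Hidden weights start at 1; the output layer starts from a closed-form
ridge regression on the unit-weight consolidation values. A gene is
**selected** when |β̂_k| exceeds a small threshold (default 0.01);
selection quality against known ground truth is summarized by
sensitivity, specificity and the Youden index J = sens + spec − 1.

## Worked example

Simulate three studies (80 genes, 16 with signal, N=100, σ=0.3), fit with
a mild penalty, and inspect the selection:

```bash
consonet simulate --sigma 0.3 --seed 7 --out demo/data
consonet train \
    --study demo/data/study_1.tsv --study demo/data/study_2.tsv \
    --study demo/data/study_3.tsv --labels demo/data/labels.txt \
    --lam 0.05 --seed 7 --out demo/fit
```

The train command prints

```
converged=False epochs=500 final_loss=0.371883 selected=6/80
```

meaning the optimizer used its full epoch budget, reached penalized loss
0.372 and called 6 of 80 genes. Comparing `demo/fit/selection.tsv`
against `demo/data/truth.tsv` shows that all 6 calls are planted signal
genes and no noise gene was called — at this fairly strong penalty the
selection is conservative but clean. A milder penalty trades precision
for recall; the same pipeline run from Python at λ=0.02 on the 70%
training split:

```python
import numpy as np
from consonet import (SimulationDesign, generate_stack, split_train_test,
                      Hyperparams, train, call_selection)

design = SimulationDesign(sigma=0.3, seed=7)
stack, truth = generate_stack(design)
train_stack, _ = split_train_test(stack, design, seed=7)
state = train(train_stack, Hyperparams(lam=0.02))
result = call_selection(state.params, truth, eps=0.01)
print(result.sensitivity, result.specificity, result.youden)
```

which prints `0.5 0.875 0.375`: half of the 16 signal genes are
recovered, 56 of the 64 noise genes are correctly left out, and the
Youden index is 0.375.

The full benchmark (30 repetitions per condition, cross-validated λ) is
one command per noise level:

```bash
consonet experiment --sigma 0.1 --sigma 0.9 --reps 30 --seed 1 --out bench/
```

writing a report TSV with columns
`method sigma n_random sensitivity se_sens specificity se_spec youden n_reps`.

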