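# Methods

## Model and estimation

`consonet` fits a one-hidden-layer network whose topology encodes gene
identity. Gene *k* owns M hidden nodes (one per study under vertical
integration; P input features per node, P=1 in the standard setting).
The hidden ReLU outputs of a gene are combined into a single
*consolidation* value through weights normalized by their Euclidean norm,
`C_ik = Σ_m w_km O_ikm / ‖w_k‖`, so the consolidation is invariant to
positive rescaling of each gene's weight vector and all cross-gene
competition happens in the output layer. A logistic output over the K
consolidation values with a lasso penalty `λ Σ_k |β_k|` (intercept
unpenalized) turns the output layer into a gene selector: genes whose
combined multi-study evidence does not help classification are shrunk to
numerically zero coefficients.

Estimation is full-batch and deterministic:

* **Initialization.** All v and w are 1. With those weights the
  consolidation matrix C is computed once and the output layer is seeded
  by the ridge closed form `(XᵀX + λ_r I)⁻¹ Xᵀy` with design `X = [1 | C]`
  (λ_r = 1 by default; the intercept is included in this one-off ridge
  shrinkage, which only supplies a starting point).
* **β update.** A simultaneous Newton-style sweep: coordinate move
  = `[Σ_i (f_i−y_i)C_ik + Nλ·sign(β_k)] / [Σ_i f_i(1−f_i)C_ik² + Nλ·z′(β_k)]`,
  where `z(β) = 2·sigmoid(β/s) − 1` (s = 10⁻³) smooths the sign so the
  penalty has curvature at 0 (`z′(0) = 1/(2s)`). Four safeguards make
  the sweep a descent step: the per-sample curvature f(1−f) is floored
  at 10⁻⁵ (the usual IRLS clip — saturated probabilities would otherwise
  zero the denominator and freeze coordinates); denominators still below
  10⁻¹⁰ fall back to a plain gradient step of size η; each coordinate
  move is clamped to 0.1; and the whole sweep is backtracked (step
  halving) until the β-subproblem objective does not increase. A damped
  move that would cross zero is truncated at zero, where the huge smooth-
  sign curvature pins small coefficients — this pinning is the mechanism
  by which the penalty produces a sparse, selectable β.
* **β₀, w, v updates.** Plain gradient steps of size η = 0.01, each from
  a freshly recomputed forward pass (order β → β₀ → w → v per epoch).
  The w gradient is the exact derivative of the normalized consolidation
  (second term scaled by ‖w‖³); `Hyperparams(exact_w_gradient=False)`
  switches to a commonly printed approximation with ‖w‖². The ReLU
  derivative at exactly 0 is taken as 0. If a w step would drive a
  gene's norm below 10⁻⁸ the step is halved until the floor holds.
* **Stopping.** At most 500 epochs, or earlier when the penalized loss
  changes by less than 10⁻⁶ per epoch. Probabilities are clipped to
  [10⁻¹², 1−10⁻¹²] before logs.

Two implementation paths exist: modular numpy operations (the reference,
unit-tested against finite differences and closed forms) and a fused
numba kernel used by `train()`; a test asserts both produce the same
trajectories.

### Why the damped simultaneous sweep

The bare per-coordinate Newton formula admits two natural executions.
Applied cyclically (Gauss–Seidel) it is a greedy coordinate descent: on
data where one gene separates the classes, the first escaping
coordinate absorbs the entire fit and the remaining (correlated) signal
genes are shrunk away — technically near-optimal for the penalized
objective, but useless for selection. Applied simultaneously without
damping it diverges outright on correlated consolidation columns. The
damped simultaneous sweep keeps the printed per-coordinate move while
letting all coordinates advance together, so correlated signal genes
share the fit the way they do under ordinary backpropagation. Selection
sensitivity in the near-degenerate weak-penalty regime is a property of
the optimizer's trajectory, not of the objective's optimum; this choice
is made explicitly and consistently.

## Penalty tuning

`cv_select_lambda` uses stratified 5-fold cross-validation over an
increasing λ grid, scoring each penalty by held-out **misclassification
error** and breaking ties toward the larger penalty (held-out deviance is
available as `criterion="deviance"`). Error is the selection-oriented
choice: when classes are widely separated, every penalty below the
collapse point classifies held-out samples perfectly, and the larger-λ
tie-break then selects the strongest penalty compatible with the signal —
the regime that separates signal from nonsignal coefficients. Deviance
instead always rewards the least-penalized, most confident fit, which is
the worst regime for selection. CV fold fits and the final fit start
cold from the ridge initialization at each λ, matching how the chosen
penalty is ultimately used; `lambda_path` (the Fig.-style path tracer)
warm-starts along the grid instead, which is faster but
trajectory-dependent.

The default benchmark grid is `logspace(-3, -1, 5)`. The upper end is
set where the zero-pin dominates every achievable data gradient — at
λ = 0.1, N = 70 the penalty curvature at zero is Nλ/(2s) = 3500, far
above any attainable data curvature, so beyond this scale every
coefficient freezes near its initialization and all fits collapse
regardless of signal (the total-shrinkage regime the λ-path utility
displays). The lower end is effectively unpenalized. Five grid points
keep a 30-repetition benchmark cell (≈ 26 fits per repetition) around
100 s on one CPU.

## Synthetic data generator

`SimulationDesign` emulates a two-class multi-study benchmark: 80 genes
per study, 16 signal (two exchangeable-correlation clusters of 8,
ρ = 0.5 within, 0 between) and 64 nonsignal, three studies, N = 100
balanced samples, 70/30 stratified train/test split. Signal genes are
drawn MVN(m, σ²Σ) with mean shift m = μ·1 (μ = 1 by default) in case
samples and 0 in controls; nonsignal genes are MVN(0, σ²I) everywhere; a
*random study* draws **all** genes MVN(0, σ²I) regardless of class,
emulating an uninformative platform. Where the emulated design leaves
parameters unstated (μ, Σ, N, the coupling of labels to the mean shift),
the defaults above were fixed once as the smallest structure consistent
with two correlated signal clusters and clear two-class separation, and
are all exposed in the configuration.

What the generator does **not** emulate: real-platform marginals
(methylation beta values, CNV discreteness), gene-gene correlation among
nonsignal genes, batch effects, or unbalanced cohorts. Passing
benchmarks on this generator therefore demonstrate correct mechanics and
qualitative robustness, not performance on real TCGA-like data.

A consequence of μ = 1 worth knowing: at σ = 0.1 the classes are
separable through any single signal gene. Selection quality then hinges
on how many signal genes the optimizer keeps, and prediction-based
tuning cannot distinguish penalties (all classify perfectly). With two
of three studies replaced by noise the signal consolidation values
shrink ≈ 2.8×, signal coefficients escape the zero-pin slowly and
asynchronously, and the first escapee saturates the probabilities and
stalls the rest — sensitivity collapses at every penalty in that corner
of the design space. The benchmark harness reports this honestly.

## Evaluation harness

`run_experiment` repeats, per repetition: generate → split 70/30
(stratified) → tune λ by CV on the training part → refit at the tuned λ →
call genes by |β̂_k| > 0.01 against the generator's truth. It reports
mean sensitivity and specificity with standard errors (sample SD/√reps)
and the mean Youden index; the Youden identity J = sens + spec − 1 holds
exactly on every emitted row. A failing repetition is skipped and
counted; more than half failing aborts. All randomness flows from one
root seed via spawned `SeedSequence`s, so reports are bit-reproducible.

## Numerical choices and edge cases

* sign(0) := 0 in the β numerator (subgradient convention); the
  non-differentiability at 0 is otherwise handled by z′ in the
  denominator only.
* Probability clipping δ = 10⁻¹² before logarithms.
* Ridge initialization raises (advising λ_r > 0) only if the system is
  singular with λ_r = 0.
* Selection uses a magnitude threshold (0.01) because the smooth
  optimizer produces numerically-but-not-exactly zero coefficients;
  zero-truncated coordinates are exact zeros.
* Architectures are rectangular (same M and P for every gene): the
  ragged general case is never exercised by the vertical-integration
  design this package targets.

## Known limitations

* The optimizer is trajectory-sensitive in near-degenerate regimes
  (strong separation, weak penalty); results there characterize the
  algorithm, not the penalized optimum.
* Single binary outcome, single hidden layer, full-batch updates only.
* Baseline methods (meta-analytic logistic regression, meta-SVM) are not
  implemented; the report format accepts externally computed baseline
  rows for side-by-side tables.
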