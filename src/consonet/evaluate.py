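"""Gene-selection calls, Youden-index metrics, penalty paths and the
repeated-simulation benchmarking harness.

A gene is *selected* when its fitted output coefficient exceeds a small
magnitude threshold (the smooth optimizer shrinks null coefficients to
numerically-but-not-exactly zero).  Against the simulator's ground truth
this yields sensitivity (fraction of signal genes selected), specificity
(fraction of nonsignal genes not selected) and the Youden J index
``sensitivity + specificity - 1``.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model import Hyperparams, NetworkParams, OmicsStack, forward, penalized_loss
from .simulate import SimulationDesign, generate_stack, split_train_test
from .training import TrainingDivergedError, train

__all__ = [
    "SelectionResult",
    "LambdaPath",
    "ExperimentError",
    "StratificationError",
    "call_selection",
    "lambda_path",
    "cv_select_lambda",
    "run_experiment",
    "simulation_table",
    "plot_lambda_path",
]

logger = logging.getLogger(__name__)

METHOD_NAME = "integrative-dl"


class ExperimentError(RuntimeError):
    """Raised when too many repetitions of an experiment fail."""


class StratificationError(ValueError):
    """Raised when stratified folds cannot contain both classes."""


@dataclasses.dataclass
class SelectionResult:
    """Per-gene selection calls with summary rates.

    ``youden`` always equals ``sensitivity + specificity - 1``.  When the
    result aggregates repeated runs, ``n_reps`` and the standard errors
    (sample SD / sqrt(n_reps)) are filled in and ``selected`` is None.
    """

    sensitivity: float
    specificity: float
    youden: float
    selected: np.ndarray | None = None
    n_reps: int | None = None
    se_sensitivity: float | None = None
    se_specificity: float | None = None

    @classmethod
    def from_rates(cls, sensitivity: float, specificity: float, **kw) -> "SelectionResult":
        return cls(
            sensitivity=sensitivity,
            specificity=specificity,
            youden=sensitivity + specificity - 1.0,
            **kw,
        )


@dataclasses.dataclass
class LambdaPath:
    """Fitted output coefficients along an increasing penalty grid.

    ``betas`` has one row per lambda (NaN rows mark divergent fits);
    ``cv_scores`` and ``lambda_opt`` are filled by cross-validation."""

    lambdas: np.ndarray
    betas: np.ndarray
    cv_scores: np.ndarray | None = None
    lambda_opt: float | None = None


def call_selection(
    params: NetworkParams,
    truth: np.ndarray,
    eps: float,
    strict: bool = False,
) -> SelectionResult:
    """Call genes by coefficient magnitude and score against ground truth.

    Sensitivity is the fraction of true signal genes with |beta_k| > eps;
    specificity the fraction of nonsignal genes with |beta_k| <= eps.  If
    the truth vector contains only one class the undefined rate is NaN
    (or an error in strict mode).
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.shape[0] != params.beta.shape[0]:
        raise ValueError("truth length must equal the number of genes")
    selected = np.abs(params.beta) > eps
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if strict and (n_pos == 0 or n_neg == 0):
        raise ValueError("truth contains a single class; sensitivity/specificity undefined")
    sens = float((selected & truth).sum() / n_pos) if n_pos else math.nan
    spec = float((~selected & ~truth).sum() / n_neg) if n_neg else math.nan
    return SelectionResult(
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        selected=selected,
    )


def _check_grid(lambdas: np.ndarray) -> np.ndarray:
    grid = np.asarray(lambdas, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("lambda grid must be strictly increasing")
    if grid[0] < 0:
        raise ValueError("lambdas must be >= 0")
    return grid


def lambda_path(
    stack: OmicsStack, hyper: Hyperparams, lambdas: np.ndarray
) -> LambdaPath:
    """Fit the network over an increasing penalty grid with warm starts.

    Each fit starts from the previous grid point's parameters, so the
    path traces how the output coefficients shrink toward zero as the
    penalty grows.  A divergent fit is recorded as a NaN row and skipped.
    """
    grid = _check_grid(lambdas)
    betas = np.full((grid.size, stack.n_genes), np.nan)
    warm: NetworkParams | None = None
    for j, lam in enumerate(grid):
        h = dataclasses.replace(hyper, lam=float(lam))
        try:
            state = train(stack, h, init=warm)
        except TrainingDivergedError as err:
            logger.warning("fit at lambda=%g diverged: %s", lam, err)
            continue
        warm = state.params
        betas[j] = state.params.beta
    return LambdaPath(lambdas=grid, betas=betas)


def cv_select_lambda(
    stack: OmicsStack,
    hyper: Hyperparams,
    lambdas: np.ndarray,
    n_folds: int = 5,
    seed: int | None = None,
    criterion: str = "error",
    warm: bool = False,
    full: bool = False,
):
    """Pick the penalty by stratified K-fold cross-validation.

    For every fold the network is fitted at each grid penalty on the
    training part and scored on the held-out part; the grid value
    minimizing the mean held-out score wins, with ties broken toward the
    larger penalty.  By default every fit starts cold from the ridge
    initialization, matching how the chosen penalty will be used for the
    final fit; ``warm=True`` chains fits along the grid instead (faster,
    but the optimizer's trajectory then depends on the whole path).

    ``criterion`` is ``"error"`` (held-out misclassification rate, the
    default) or ``"deviance"`` (held-out unpenalized cross-entropy).
    Error is the selection-oriented choice: when the classes are widely
    separated every penalty below the shrink-everything point classifies
    held-out samples equally well, and the larger-penalty tie-break then
    lands at the strongest penalty compatible with the signal — the
    regime that separates signal from nonsignal genes.  Deviance instead
    always rewards the least-penalized, most confident fit.
    """
    grid = _check_grid(lambdas)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if criterion not in ("error", "deviance"):
        raise ValueError("criterion must be 'error' or 'deviance'")
    counts = np.bincount(stack.labels, minlength=2)
    if counts.min() < n_folds:
        raise StratificationError(
            f"cannot build {n_folds} stratified folds with class counts {counts.tolist()}"
        )
    if seed is None:
        seed = hyper.seed
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((n_folds, grid.size))
    for fold, (tr, va) in enumerate(splitter.split(np.zeros(stack.n_samples), stack.labels)):
        fit_stack, val_stack = stack.subset(tr), stack.subset(va)
        prev: NetworkParams | None = None
        for j, lam in enumerate(grid):
            h = dataclasses.replace(hyper, lam=float(lam))
            try:
                state = train(fit_stack, h, init=prev)
            except TrainingDivergedError:
                scores[fold, j] = np.inf
                continue
            if warm:
                prev = state.params
            f = forward(val_stack, state.params).f
            if criterion == "error":
                scores[fold, j] = float(np.mean((f >= 0.5) != (val_stack.labels == 1)))
            else:
                scores[fold, j] = penalized_loss(f, val_stack.labels, state.params, lam=0.0)
    mean_scores = scores.mean(axis=0)
    best = mean_scores.min()
    lam_opt = float(grid[np.flatnonzero(mean_scores <= best + 1e-12).max()])
    if full:
        return lam_opt, mean_scores
    return lam_opt


def run_experiment(
    design: SimulationDesign,
    hyper: Hyperparams,
    lambdas: np.ndarray,
    n_reps: int = 30,
    seed: int | None = None,
    n_folds: int = 5,
    cv_criterion: str = "error",
    return_reps: bool = False,
):
    """Repeat the full selection pipeline and aggregate the rates.

    Each repetition draws a fresh dataset, splits it 70/30 (stratified),
    tunes the penalty by cross-validation on the training part, refits at
    the tuned penalty and calls genes against the generator's truth.
    Returns a one-row table (method, sigma, n_random, sensitivity,
    se_sens, specificity, se_spec, youden, n_reps); standard errors are
    sample SD / sqrt(n_reps).  A failing repetition is skipped and
    counted; more than half failing aborts the experiment.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.SeedSequence(seed if seed is not None else design.seed)
    sens, spec = [], []
    n_skipped = 0
    for rep, child in enumerate(root.spawn(n_reps)):
        ss_gen, ss_split, ss_cv = child.spawn(3)
        try:
            stack, truth = generate_stack(design, rng=np.random.default_rng(ss_gen))
            train_stack, _ = split_train_test(
                stack, design, seed=int(ss_split.generate_state(1)[0] % 2**31)
            )
            lam_opt = cv_select_lambda(
                train_stack,
                hyper,
                lambdas,
                n_folds=n_folds,
                seed=int(ss_cv.generate_state(1)[0] % 2**31),
                criterion=cv_criterion,
            )
            state = train(train_stack, dataclasses.replace(hyper, lam=lam_opt))
            res = call_selection(state.params, truth, hyper.select_eps, strict=True)
        except Exception as err:  # noqa: BLE001 — any fatal repetition is skipped
            logger.warning("repetition %d failed and was skipped: %s", rep, err)
            n_skipped += 1
            continue
        sens.append(res.sensitivity)
        spec.append(res.specificity)
    if n_skipped > n_reps / 2:
        raise ExperimentError(
            f"{n_skipped} of {n_reps} repetitions failed; experiment aborted"
        )
    n_done = len(sens)
    sens_arr, spec_arr = np.asarray(sens), np.asarray(spec)
    se = lambda x: float(np.std(x, ddof=1) / math.sqrt(n_done)) if n_done > 1 else 0.0
    summary = SelectionResult.from_rates(
        float(sens_arr.mean()),
        float(spec_arr.mean()),
        n_reps=n_done,
        se_sensitivity=se(sens_arr),
        se_specificity=se(spec_arr),
    )
    row = pd.DataFrame(
        [
            {
                "method": METHOD_NAME,
                "sigma": design.sigma,
                "n_random": design.n_random_studies,
                "sensitivity": summary.sensitivity,
                "se_sens": summary.se_sensitivity,
                "specificity": summary.specificity,
                "se_spec": summary.se_specificity,
                "youden": summary.youden,
                "n_reps": n_done,
            }
        ]
    )
    if return_reps:
        reps = pd.DataFrame({"sensitivity": sens_arr, "specificity": spec_arr})
        reps["youden"] = reps["sensitivity"] + reps["specificity"] - 1.0
        return row, reps
    return row


def simulation_table(
    design: SimulationDesign,
    hyper: Hyperparams,
    lambdas: np.ndarray,
    sigmas,
    n_reps: int = 30,
    seed: int | None = None,
    n_folds: int = 5,
    cv_criterion: str = "error",
) -> pd.DataFrame:
    """Benchmark table over a grid of noise scales (one row per sigma)."""
    sigmas = list(sigmas)
    root = np.random.SeedSequence(seed if seed is not None else design.seed)
    rows = []
    for sigma, child in zip(sigmas, root.spawn(len(sigmas))):
        d = dataclasses.replace(design, sigma=float(sigma))
        rows.append(
            run_experiment(
                d,
                hyper,
                lambdas,
                n_reps=n_reps,
                seed=int(child.generate_state(1)[0] % 2**31),
                n_folds=n_folds,
                cv_criterion=cv_criterion,
            )
        )
    return pd.concat(rows, ignore_index=True)


def plot_lambda_path(path: LambdaPath, truth: np.ndarray | None = None, ax=None):
    """Plot |beta_k| trajectories along the penalty grid.

    Signal genes (per ``truth``) are drawn solid, nonsignal dashed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k in range(path.betas.shape[1]):
        is_sig = bool(truth[k]) if truth is not None else True
        ax.plot(
            path.lambdas,
            np.abs(path.betas[:, k]),
            color="C0" if is_sig else "C1",
            linestyle="-" if is_sig else "--",
            alpha=0.7 if is_sig else 0.4,
        )
    ax.set_xlabel("lambda")
    ax.set_ylabel("|beta_k|")
    return ax
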