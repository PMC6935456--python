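"""Initialization and full-batch backpropagation for the consolidation network.

The output layer is initialized from a closed-form ridge regression of the
labels on the unit-weight consolidation values; each training epoch then
applies, in order and each from a freshly recomputed forward pass,

1. a diagonal Newton-style update of the lasso-penalized output weights
   ``beta`` (curvature smoothed at 0 through the smooth sign derivative),
2. a gradient step on the intercept ``beta0``,
3. a gradient step on the consolidation weights ``w`` (exact derivative of
   the norm-normalized combination),
4. a gradient step on the input weights ``v`` (through the ReLU).

All updates are full-batch and deterministic; training stops at ``epochs``
or when the penalized loss changes by less than ``tol``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from ._engine import train_kernel
from .model import (
    Hyperparams,
    NetworkParams,
    OmicsStack,
    ForwardCache,
    forward,
    penalized_loss,
    smooth_sign,
)

__all__ = [
    "TrainState",
    "TrainingDivergedError",
    "init_params",
    "grad_beta",
    "grad_beta0",
    "grad_w",
    "grad_v",
    "update_beta",
    "update_beta0",
    "update_w",
    "update_v",
    "train",
]

logger = logging.getLogger(__name__)

#: Newton denominators below this floor trigger a plain gradient step.
NEWTON_DENOM_FLOOR = 1e-10
#: Maximum magnitude of a single coordinate move of the output weights.
#: A small cap makes the output coefficients grow collectively (many
#: correlated genes share the fit) instead of letting one coordinate
#: saturate the predictions within an epoch.
BETA_STEP_CAP = 0.1
#: Per-sample Bernoulli curvature f(1-f) is floored at this value.
CURVATURE_FLOOR = 1e-5
#: Per-gene consolidation weight norms are kept above this floor.
W_NORM_FLOOR = 1e-8


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclasses.dataclass
class TrainState:
    """Result of a training run.

    ``loss_history`` holds the penalized loss before training and after
    every completed epoch, so its length is ``epoch + 1``.
    """

    params: NetworkParams
    epoch: int
    loss_history: list[float]
    converged: bool


def init_params(stack: OmicsStack, hyper: Hyperparams) -> NetworkParams:
    """Systematic initialization: unit hidden weights, ridge output layer.

    All ``v`` and ``w`` are set to 1; the consolidation values C under
    those unit weights form (with a leading 1-column) the design matrix of
    a ridge regression on the labels, whose closed-form solution
    ``(X'X + ridge_lam*I)^-1 X'y`` seeds ``beta0`` and ``beta``.
    """
    if stack.n_samples < 2:
        raise ValueError("at least two samples are required")
    if len(np.unique(stack.labels)) < 2:
        raise ValueError("labels must contain both classes")
    params = NetworkParams.unit(stack.arch)
    C = forward(stack, params).C
    X = np.column_stack([np.ones(stack.n_samples), C])
    A = X.T @ X + hyper.ridge_lam * np.eye(X.shape[1])
    try:
        coef = np.linalg.solve(A, X.T @ stack.labels.astype(float))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "ridge initialization system is singular; set ridge_lam > 0"
        ) from err
    return NetworkParams(v=params.v, w=params.w, beta0=float(coef[0]), beta=coef[1:])


def grad_beta(
    cache: ForwardCache, labels: np.ndarray, params: NetworkParams, lam: float
) -> np.ndarray:
    """Subgradient of the penalized loss w.r.t. the output weights.

    (1/N) sum_i (f_i - y_i) C[i,k] + lam * sign(beta_k), with sign(0) = 0.
    """
    n = labels.shape[0]
    return (cache.f - labels) @ cache.C / n + lam * np.sign(params.beta)


def grad_beta0(cache: ForwardCache, labels: np.ndarray) -> float:
    """Gradient of the loss w.r.t. the intercept: mean residual."""
    return float(np.mean(cache.f - labels))


def grad_w(
    cache: ForwardCache,
    labels: np.ndarray,
    params: NetworkParams,
    exact: bool = True,
) -> np.ndarray:
    """Gradient w.r.t. the consolidation weights.

    The exact derivative of C[i,k] = w.O / ||w|| w.r.t. w_m is
    O_m/||w|| - w_m * (w.O) / ||w||^3; with ``exact=False`` the second
    term's norm power drops to 2, reproducing a commonly printed
    approximation. The exact form is orthogonal to w (the normalized
    consolidation is scale-free in w).
    """
    n = labels.shape[0]
    r = cache.f - labels
    norms = np.linalg.norm(params.w, axis=1)
    wo = np.einsum("km,ikm->ik", params.w, cache.O)  # w.O per (sample, gene)
    t1 = np.einsum("i,ikm->km", r, cache.O)
    u = r @ wo  # per-gene sum_i r_i (w.O)_i
    power = 3 if exact else 2
    grad = (params.beta / norms)[:, None] * t1 / n
    grad -= ((params.beta * u) / norms**power)[:, None] * params.w / n
    return grad


def grad_v(
    cache: ForwardCache,
    stack: OmicsStack,
    labels: np.ndarray,
    params: NetworkParams,
) -> np.ndarray:
    """Gradient w.r.t. the input weights, through the ReLU.

    The ReLU derivative at exactly 0 is taken as 0.
    """
    n = labels.shape[0]
    r = cache.f - labels
    act = (cache.a > 0.0).astype(float)
    norms = np.linalg.norm(params.w, axis=1)
    factor = params.beta[:, None] * params.w / norms[:, None]  # (K, M)
    t = np.einsum("ikm,ikmp->kmp", r[:, None, None] * act, stack.values)
    return t * factor[:, :, None] / n


def _beta_objective(
    C: np.ndarray, y: np.ndarray, beta: np.ndarray, beta0: float, lam: float
) -> float:
    from scipy.special import expit

    f = np.clip(expit(beta0 + C @ beta), 1e-12, 1.0 - 1e-12)
    ce = -float(np.mean(y * np.log(f) + (1.0 - y) * np.log(1.0 - f)))
    return ce + lam * float(np.abs(beta).sum())


def update_beta(
    cache: ForwardCache,
    labels: np.ndarray,
    params: NetworkParams,
    hyper: Hyperparams,
) -> NetworkParams:
    """Damped Newton-style simultaneous update of the output weights.

    Every coordinate's proposed move is numerator/denominator: the
    numerator sums residual-times-C plus N*lam*sign(beta_k) and the
    denominator sums the Bernoulli curvature times C^2 plus N*lam*
    z'(beta_k).  Three safeguards make the simultaneous sweep a descent
    step on the beta-subproblem (with C and the intercept held fixed):

    * the per-sample curvature f(1-f) is floored at 1e-5 (the usual IRLS
      clip), so saturated probabilities cannot zero the denominator and
      freeze the coordinate — denominators still below a small floor fall
      back to a plain gradient step of size eta;
    * each coordinate move is clamped to a small maximum magnitude, so
      correlated coordinates advance together instead of one saturating
      the predictions within a single sweep;
    * the whole sweep is scaled by a backtracking factor (halved until
      the penalized beta-subproblem loss does not increase), because
      simultaneous full diagonal-Newton moves of strongly correlated
      coordinates overshoot.

    A damped move that would cross zero is truncated at zero: the
    sign(beta_k) term it was computed with is invalid past the crossing,
    and the smooth-sign curvature z'(0) = 1/(2s) then holds small
    coefficients there — which is exactly how the penalty effects gene
    selection.
    """
    n = labels.shape[0]
    y = labels.astype(float)
    C = cache.C
    beta = params.beta
    num = (cache.f - y) @ C + n * hyper.lam * np.sign(beta)
    wgt = np.maximum(cache.f * (1.0 - cache.f), CURVATURE_FLOOR)
    _, dz = smooth_sign(beta, hyper.s)
    den = wgt @ C**2 + n * hyper.lam * dz
    with np.errstate(divide="ignore", invalid="ignore"):
        step = np.where(den >= NEWTON_DENOM_FLOOR, num / den, hyper.eta * num / n)
    step = np.clip(step, -BETA_STEP_CAP, BETA_STEP_CAP)
    bad = ~np.isfinite(step)
    if bad.any():
        logger.warning("rejecting non-finite beta update for %d gene(s)", int(bad.sum()))
        step = np.where(bad, 0.0, step)
    current = _beta_objective(C, y, beta, params.beta0, hyper.lam)
    alpha = 1.0
    new_beta = beta
    for _ in range(25):
        candidate = beta - alpha * step
        if hyper.lam > 0.0:
            crossed = (beta != 0.0) & (candidate * beta < 0.0)
            candidate = np.where(crossed, 0.0, candidate)
        if _beta_objective(C, y, candidate, params.beta0, hyper.lam) <= current:
            new_beta = candidate
            break
        alpha *= 0.5
    return dataclasses.replace(params, beta=new_beta)


def update_beta0(
    cache: ForwardCache,
    labels: np.ndarray,
    params: NetworkParams,
    hyper: Hyperparams,
) -> NetworkParams:
    """Gradient step on the intercept."""
    return dataclasses.replace(
        params, beta0=params.beta0 - hyper.eta * grad_beta0(cache, labels)
    )


def update_w(
    cache: ForwardCache,
    labels: np.ndarray,
    params: NetworkParams,
    hyper: Hyperparams,
) -> NetworkParams:
    """Gradient step on the consolidation weights with a norm safeguard.

    If a full step would drive some gene's ||w_k|| below a small floor
    (making the normalized consolidation ill-defined), that gene's step is
    halved until the floor is respected.
    """
    grad = grad_w(cache, labels, params, exact=hyper.exact_w_gradient)
    new_w = params.w - hyper.eta * grad
    norms = np.linalg.norm(new_w, axis=1)
    low = np.flatnonzero(norms < W_NORM_FLOOR)
    for k in low:
        scale = 0.5
        row = params.w[k] - scale * hyper.eta * grad[k]
        while np.linalg.norm(row) < W_NORM_FLOOR and scale > 1e-6:
            scale *= 0.5
            row = params.w[k] - scale * hyper.eta * grad[k]
        if np.linalg.norm(row) < W_NORM_FLOOR:
            row = params.w[k]
        logger.warning(
            "consolidation weight step for gene index %d rescaled to keep ||w|| above %g",
            int(k),
            W_NORM_FLOOR,
        )
        new_w[k] = row
    return dataclasses.replace(params, w=new_w)


def update_v(
    cache: ForwardCache,
    stack: OmicsStack,
    labels: np.ndarray,
    params: NetworkParams,
    hyper: Hyperparams,
) -> NetworkParams:
    """Gradient step on the input weights."""
    return dataclasses.replace(
        params, v=params.v - hyper.eta * grad_v(cache, stack, labels, params)
    )


def train(
    stack: OmicsStack,
    hyper: Hyperparams,
    init: NetworkParams | None = None,
) -> TrainState:
    """Fit the network by alternating feedforward and the four updates.

    Parameters
    ----------
    stack : OmicsStack
        Training data; both classes must be present.
    hyper : Hyperparams
        Penalty, learning rate, epoch budget and stopping tolerance.
    init : NetworkParams, optional
        Warm-start parameters (e.g. the previous fit on a penalty path);
        by default the ridge initialization is computed from the data.

    Returns
    -------
    TrainState
        Final parameters, epochs completed, loss history and a flag
        telling whether the ``tol`` stopping rule fired.
    """
    if len(np.unique(stack.labels)) < 2:
        raise ValueError("labels must contain both classes")
    params = init.copy() if init is not None else init_params(stack, hyper)
    x = np.ascontiguousarray(stack.values)
    y = stack.labels.astype(float)
    beta0_arr = np.array([params.beta0])
    loss_out = np.full(hyper.epochs + 1, np.nan)
    epoch, flag = train_kernel(
        x,
        y,
        params.v,
        params.w,
        params.beta,
        beta0_arr,
        float(hyper.lam),
        float(hyper.eta),
        float(hyper.s),
        int(hyper.epochs),
        float(hyper.tol),
        bool(hyper.exact_w_gradient),
        BETA_STEP_CAP,
        CURVATURE_FLOOR,
        NEWTON_DENOM_FLOOR,
        W_NORM_FLOOR,
        loss_out,
    )
    if flag == -1:
        raise TrainingDivergedError(
            f"penalized loss became non-finite at epoch {epoch} (eta={hyper.eta}); "
            "reduce eta or the penalty"
        )
    params.beta0 = float(beta0_arr[0])
    history = loss_out[: epoch + 1].tolist()
    converged = flag == 1
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "trained %d epochs (converged=%s) final loss=%.6g |beta|_1=%.4g n_active=%d",
            epoch,
            converged,
            history[-1],
            float(np.abs(params.beta).sum()),
            int((np.abs(params.beta) > hyper.select_eps).sum()),
        )
    return TrainState(params=params, epoch=epoch, loss_history=history, converged=converged)
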