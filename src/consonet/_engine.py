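"""Fused training loop compiled with numba.

``train_kernel`` runs the same epoch sequence as the modular operations in
:mod:`consonet.training` (damped simultaneous Newton pass on beta, then
gradient steps on beta0, w and v, each from a freshly recomputed forward
pass) but fused into one compiled loop, which matters for the
repeated-simulation benchmarks (thousands of fits).  The modular numpy
implementations remain the reference; a test asserts both paths produce
the same trajectories.
"""

from __future__ import annotations

import math

import numba
import numpy as np

PROB_FLOOR = 1e-12


@numba.njit(cache=True)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@numba.njit(cache=True)
def _forward(x, v, w, beta0, beta, a, O, C, yhat, f):
    n, k_g, m_g, p_g = x.shape
    for k in range(k_g):
        norm = 0.0
        for m in range(m_g):
            norm += w[k, m] * w[k, m]
        norm = math.sqrt(norm)
        for i in range(n):
            c = 0.0
            for m in range(m_g):
                acc = 0.0
                for p in range(p_g):
                    acc += v[k, m, p] * x[i, k, m, p]
                a[i, k, m] = acc
                o = acc if acc > 0.0 else 0.0
                O[i, k, m] = o
                c += w[k, m] * o
            C[i, k] = c / norm
    for i in range(n):
        acc = beta0
        for k in range(k_g):
            acc += beta[k] * C[i, k]
        yhat[i] = acc
        f[i] = _sigmoid(acc)


@numba.njit(cache=True)
def _loss(f, y, beta, lam):
    n = f.shape[0]
    ce = 0.0
    for i in range(n):
        fi = f[i]
        if fi < PROB_FLOOR:
            fi = PROB_FLOOR
        elif fi > 1.0 - PROB_FLOOR:
            fi = 1.0 - PROB_FLOOR
        ce -= y[i] * math.log(fi) + (1.0 - y[i]) * math.log(1.0 - fi)
    pen = 0.0
    for k in range(beta.shape[0]):
        pen += abs(beta[k])
    return ce / n + lam * pen


@numba.njit(cache=True)
def _beta_objective(C, y, beta, beta0, lam):
    n, k_g = C.shape
    ce = 0.0
    for i in range(n):
        acc = beta0
        for k in range(k_g):
            acc += beta[k] * C[i, k]
        fi = _sigmoid(acc)
        if fi < PROB_FLOOR:
            fi = PROB_FLOOR
        elif fi > 1.0 - PROB_FLOOR:
            fi = 1.0 - PROB_FLOOR
        ce -= y[i] * math.log(fi) + (1.0 - y[i]) * math.log(1.0 - fi)
    pen = 0.0
    for k in range(k_g):
        pen += abs(beta[k])
    return ce / n + lam * pen


@numba.njit(cache=True)
def train_kernel(
    x,
    y,
    v,
    w,
    beta,
    beta0_arr,
    lam,
    eta,
    s,
    epochs,
    tol,
    exact_w,
    step_cap,
    curvature_floor,
    denom_floor,
    w_norm_floor,
    loss_out,
):
    """Run up to ``epochs`` training sweeps in place.

    Returns (epochs_completed, converged_flag).  ``loss_out`` must have
    length epochs+1; entry 0 receives the initial penalized loss and entry
    e the loss after epoch e.  ``beta0_arr`` is a length-1 array so the
    intercept can be updated in place.
    """
    n, k_g, m_g, p_g = x.shape
    a = np.empty((n, k_g, m_g))
    O = np.empty((n, k_g, m_g))
    C = np.empty((n, k_g))
    yhat = np.empty(n)
    f = np.empty(n)
    num = np.empty(k_g)
    den = np.empty(k_g)
    step = np.empty(k_g)
    cand = np.empty(k_g)
    norms = np.empty(k_g)
    grad_w = np.empty((k_g, m_g))

    _forward(x, v, w, beta0_arr[0], beta, a, O, C, yhat, f)
    loss_out[0] = _loss(f, y, beta, lam)
    prev = loss_out[0]
    converged = False
    epoch = 0
    for epoch in range(1, epochs + 1):
        # ---- beta: damped simultaneous Newton pass --------------------
        for k in range(k_g):
            nk = 0.0
            dk = 0.0
            for i in range(n):
                r = f[i] - y[i]
                nk += r * C[i, k]
                wgt = f[i] * (1.0 - f[i])
                if wgt < curvature_floor:
                    wgt = curvature_floor
                dk += wgt * C[i, k] * C[i, k]
            sgn = 0.0
            if beta[k] > 0.0:
                sgn = 1.0
            elif beta[k] < 0.0:
                sgn = -1.0
            nk += n * lam * sgn
            e = math.exp(-abs(beta[k]) / s)
            dk += n * lam * (2.0 / s) * e / ((1.0 + e) * (1.0 + e))
            num[k] = nk
            den[k] = dk
            if dk >= denom_floor:
                st = nk / dk
            else:
                st = eta * nk / n
            if st > step_cap:
                st = step_cap
            elif st < -step_cap:
                st = -step_cap
            if not math.isfinite(st):
                st = 0.0
            step[k] = st
        current = _beta_objective(C, y, beta, beta0_arr[0], lam)
        alpha = 1.0
        accepted = False
        for _ in range(25):
            for k in range(k_g):
                ck = beta[k] - alpha * step[k]
                if lam > 0.0 and beta[k] != 0.0 and ck * beta[k] < 0.0:
                    ck = 0.0
                cand[k] = ck
            if _beta_objective(C, y, cand, beta0_arr[0], lam) <= current:
                accepted = True
                break
            alpha *= 0.5
        if accepted:
            for k in range(k_g):
                beta[k] = cand[k]
        _forward(x, v, w, beta0_arr[0], beta, a, O, C, yhat, f)

        # ---- beta0: gradient step ------------------------------------
        g0 = 0.0
        for i in range(n):
            g0 += f[i] - y[i]
        beta0_arr[0] -= eta * g0 / n
        _forward(x, v, w, beta0_arr[0], beta, a, O, C, yhat, f)

        # ---- w: gradient step with norm safeguard --------------------
        for k in range(k_g):
            nrm = 0.0
            for m in range(m_g):
                nrm += w[k, m] * w[k, m]
            norms[k] = math.sqrt(nrm)
        for k in range(k_g):
            u = 0.0
            for i in range(n):
                wo = 0.0
                for m in range(m_g):
                    wo += w[k, m] * O[i, k, m]
                u += (f[i] - y[i]) * wo
            if exact_w:
                power = norms[k] ** 3
            else:
                power = norms[k] ** 2
            for m in range(m_g):
                t1 = 0.0
                for i in range(n):
                    t1 += (f[i] - y[i]) * O[i, k, m]
                grad_w[k, m] = (
                    beta[k] / norms[k] * t1 / n - beta[k] * u / power * w[k, m] / n
                )
        for k in range(k_g):
            nrm = 0.0
            for m in range(m_g):
                nw = w[k, m] - eta * grad_w[k, m]
                nrm += nw * nw
            if math.sqrt(nrm) >= w_norm_floor:
                for m in range(m_g):
                    w[k, m] -= eta * grad_w[k, m]
            else:
                scale = 0.5
                ok = False
                while scale > 1e-6:
                    nrm = 0.0
                    for m in range(m_g):
                        nw = w[k, m] - scale * eta * grad_w[k, m]
                        nrm += nw * nw
                    if math.sqrt(nrm) >= w_norm_floor:
                        ok = True
                        break
                    scale *= 0.5
                if ok:
                    for m in range(m_g):
                        w[k, m] -= scale * eta * grad_w[k, m]
        _forward(x, v, w, beta0_arr[0], beta, a, O, C, yhat, f)

        # ---- v: gradient step ----------------------------------------
        for k in range(k_g):
            nrm = 0.0
            for m in range(m_g):
                nrm += w[k, m] * w[k, m]
            nrm = math.sqrt(nrm)
            for m in range(m_g):
                factor = beta[k] * w[k, m] / nrm
                for p in range(p_g):
                    g = 0.0
                    for i in range(n):
                        if a[i, k, m] > 0.0:
                            g += (f[i] - y[i]) * x[i, k, m, p]
                    v[k, m, p] -= eta * factor * g / n
        _forward(x, v, w, beta0_arr[0], beta, a, O, C, yhat, f)

        loss = _loss(f, y, beta, lam)
        if not math.isfinite(loss):
            return epoch, -1
        loss_out[epoch] = loss
        if abs(loss - prev) < tol:
            converged = True
            break
        prev = loss
    return epoch, (1 if converged else 0)
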