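"""Initialization, analytic gradients and the training loop."""

import dataclasses
import math

import numpy as np
import pytest

from consonet.model import (
    Hyperparams,
    NetworkParams,
    OmicsStack,
    ForwardCache,
    forward,
    penalized_loss,
)
from consonet.simulate import SimulationDesign, generate_stack
from consonet.training import (
    grad_beta,
    grad_beta0,
    grad_v,
    grad_w,
    init_params,
    train,
    update_beta,
    update_beta0,
)

from conftest import make_params


def loss_of(stack, params, lam):
    return penalized_loss(forward(stack, params).f, stack.labels, params, lam)


def central_difference(fun, x0, h=1e-6):
    return (fun(x0 + h) - fun(x0 - h)) / (2.0 * h)


class TestInit:
    def test_hidden_weights_are_all_ones(self, small_instance):
        stack, _ = small_instance
        params = init_params(stack, Hyperparams())
        assert np.all(params.v == 1.0)
        assert np.all(params.w == 1.0)

    def test_infinite_shrinkage_limit(self, small_instance):
        stack, _ = small_instance
        params = init_params(stack, Hyperparams(ridge_lam=1e12))
        assert abs(params.beta0) < 1e-6
        assert np.all(np.abs(params.beta) < 1e-6)

    def test_matches_closed_form_on_hand_system(self):
        """K=1, N=4: the ridge solution equals an explicit 2x2 inverse."""
        # one gene, one study, one feature; v=w=1 so C equals relu(x)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        stack = OmicsStack(values=x.reshape(4, 1, 1, 1), labels=y.astype(int))
        lam = 0.7
        params = init_params(stack, Hyperparams(ridge_lam=lam))

        X = np.column_stack([np.ones(4), x])
        A = X.T @ X + lam * np.eye(2)
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        Ainv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
        expected = Ainv @ (X.T @ y)
        assert params.beta0 == pytest.approx(expected[0], rel=1e-10)
        assert params.beta[0] == pytest.approx(expected[1], rel=1e-10)

    def test_requires_both_classes(self, rng):
        stack = OmicsStack(values=rng.normal(size=(4, 2, 1, 1)), labels=np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            init_params(stack, Hyperparams())


class TestGradients:
    """Every analytic gradient matches central finite differences."""

    def test_grad_beta_matches_finite_differences(self, kink_free_instance):
        stack, params = kink_free_instance
        lam = 0.2
        cache = forward(stack, params)
        grad = grad_beta(cache, stack.labels, params, lam)
        for k in range(params.beta.size):
            def fun(b, k=k):
                p = params.copy()
                p.beta[k] = b
                return loss_of(stack, p, lam)

            fd = central_difference(fun, params.beta[k])
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_grad_beta_trivial_forms(self, rng):
        # zero residual: gradient reduces to the penalty subgradient
        C = rng.normal(size=(4, 2))
        f = np.array([0.3, 0.6, 0.2, 0.9])
        cache = ForwardCache(a=None, O=None, C=C, yhat=None, f=f.copy())
        params = make_params(rng, k=2, m=2, p=2)
        params.beta[:] = [1.5, -0.4]
        grad = grad_beta(cache, f, params, lam=0.7)
        np.testing.assert_allclose(grad, [0.7, -0.7], atol=1e-12)
        # single sample, no penalty
        cache1 = ForwardCache(a=None, O=None, C=C[:1], yhat=None, f=np.array([0.8]))
        g1 = grad_beta(cache1, np.array([0.0]), params, lam=0.0)
        np.testing.assert_allclose(g1, 0.8 * C[0], rtol=1e-12)

    def test_grad_beta0_matches_finite_differences(self, kink_free_instance):
        stack, params = kink_free_instance
        cache = forward(stack, params)
        grad = grad_beta0(cache, stack.labels)

        def fun(b0):
            p = params.copy()
            p.beta0 = b0
            return loss_of(stack, p, 0.0)

        assert grad == pytest.approx(central_difference(fun, params.beta0), rel=1e-5)

    def test_grad_w_matches_finite_differences(self, kink_free_instance):
        stack, params = kink_free_instance
        cache = forward(stack, params)
        grad = grad_w(cache, stack.labels, params, exact=True)
        for k in range(params.w.shape[0]):
            for m in range(params.w.shape[1]):
                def fun(wv, k=k, m=m):
                    p = params.copy()
                    p.w[k, m] = wv
                    return loss_of(stack, p, 0.0)

                fd = central_difference(fun, params.w[k, m])
                assert grad[k, m] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_grad_w_orthogonal_to_w(self, kink_free_instance):
        """Degree-0 homogeneity makes the exact w-gradient orthogonal to w."""
        stack, params = kink_free_instance
        cache = forward(stack, params)
        grad = grad_w(cache, stack.labels, params, exact=True)
        dots = np.einsum("km,km->k", params.w, grad)
        np.testing.assert_allclose(dots, 0.0, atol=1e-12)

    def test_grad_w_zero_for_zero_beta(self, kink_free_instance):
        stack, params = kink_free_instance
        params.beta[1] = 0.0
        cache = forward(stack, params)
        grad = grad_w(cache, stack.labels, params)
        np.testing.assert_allclose(grad[1], 0.0, atol=1e-15)

    def test_grad_v_matches_finite_differences(self, kink_free_instance):
        stack, params = kink_free_instance
        cache = forward(stack, params)
        grad = grad_v(cache, stack, stack.labels, params)
        k_g, m_g, p_g = params.v.shape
        for k in range(k_g):
            for m in range(m_g):
                for p in range(p_g):
                    def fun(vv, k=k, m=m, p=p):
                        pp = params.copy()
                        pp.v[k, m, p] = vv
                        return loss_of(stack, pp, 0.0)

                    fd = central_difference(fun, params.v[k, m, p])
                    assert grad[k, m, p] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_grad_v_dead_relu_and_zero_input(self, rng):
        params = make_params(rng, k=1, m=1, p=1)
        params.v[:] = 1.0
        # all pre-activations negative: dead ReLU, zero gradient
        stack = OmicsStack(values=-np.abs(rng.normal(size=(5, 1, 1, 1))) - 0.1,
                           labels=np.array([0, 1, 0, 1, 1]))
        cache = forward(stack, params)
        assert np.all(grad_v(cache, stack, stack.labels, params) == 0.0)
        # zero regressor: zero gradient
        stack0 = OmicsStack(values=np.zeros((4, 1, 1, 1)), labels=np.array([0, 1, 0, 1]))
        cache0 = forward(stack0, params)
        assert np.all(grad_v(cache0, stack0, stack0.labels, params) == 0.0)


class TestUpdates:
    def test_beta_fixed_point_at_zero_numerator(self, rng):
        """Zero residual-projection and zero penalty leave beta unchanged."""
        params = make_params(rng, k=1, m=1, p=1)
        # two samples with equal C and residuals +-0.5 cancel exactly
        C = np.array([[2.0], [2.0]])
        f = np.array([0.5, 0.5])
        y = np.array([0, 1])
        cache = ForwardCache(a=None, O=None, C=C, yhat=np.zeros(2), f=f)
        new = update_beta(cache, y, params, Hyperparams(lam=0.0))
        assert new.beta[0] == params.beta[0]

    def test_beta_update_matches_scalar_newton_step(self):
        """N=3, K=1: the damped pass reduces to one scalar Newton step."""
        C = np.array([[1.0], [2.0], [-1.0]])
        y = np.array([1, 0, 1])
        beta = np.array([-0.7])
        beta0 = 0.1
        params = NetworkParams(v=np.ones((1, 1, 1)), w=np.ones((1, 1)), beta0=beta0, beta=beta.copy())
        lam, s = 0.02, 1e-3
        yhat = beta0 + C[:, 0] * beta[0]
        f = 1.0 / (1.0 + np.exp(-yhat))
        cache = ForwardCache(a=None, O=None, C=C, yhat=yhat, f=f)

        num = float((f - y) @ C[:, 0]) + 3 * lam * np.sign(beta[0])
        sig = 1.0 / (1.0 + math.exp(-beta[0] / s))
        den = float((f * (1 - f)) @ C[:, 0] ** 2) + 3 * lam * (2 / s) * sig * (1 - sig)
        expected = beta[0] - num / den

        new = update_beta(cache, y, params, Hyperparams(lam=lam, s=s))
        assert new.beta[0] == pytest.approx(expected, rel=1e-12)

    def test_beta0_step_and_zero_residual(self, rng):
        params = make_params(rng, k=2, m=1, p=1)
        f = np.array([0.2, 0.8, 0.5])
        cache = ForwardCache(a=None, O=None, C=np.zeros((3, 2)), yhat=None, f=f)
        # residuals f - y sum to zero: intercept unchanged
        y = np.array([0.2, 0.8, 0.5])
        new = update_beta0(cache, y, params, Hyperparams(eta=0.3))
        assert new.beta0 == params.beta0
        # otherwise moves against the mean residual
        y2 = np.array([0, 1, 1])
        new2 = update_beta0(cache, y2, params, Hyperparams(eta=0.3))
        assert new2.beta0 == pytest.approx(params.beta0 - 0.3 * np.mean(f - y2))

    def test_beta_subproblem_solves_logistic_regression(self):
        """With w, v frozen and lam=0, repeated beta/beta0 updates reach the
        logistic regression on C fitted by an independent solver."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n, k = 200, 3
        C = np.abs(rng.normal(size=(n, k)))  # consolidation values are >= 0
        truth_beta = np.array([1.0, -2.0, 0.5])
        logits = -0.3 + C @ truth_beta
        y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)

        params = NetworkParams(
            v=np.ones((k, 1, 1)), w=np.ones((k, 1)), beta0=0.0, beta=np.zeros(k)
        )
        hyper = Hyperparams(lam=0.0, eta=0.5)
        cache = ForwardCache(a=None, O=None, C=C, yhat=None, f=None)
        for _ in range(4000):
            yhat = params.beta0 + C @ params.beta
            cache = ForwardCache(a=None, O=None, C=C, yhat=yhat, f=1 / (1 + np.exp(-yhat)))
            params = update_beta(cache, y, params, hyper)
            yhat = params.beta0 + C @ params.beta
            cache = ForwardCache(a=None, O=None, C=C, yhat=yhat, f=1 / (1 + np.exp(-yhat)))
            params = update_beta0(cache, y, params, hyper)

        fit = sm.Logit(y, np.column_stack([np.ones(n), C])).fit(disp=0)
        reference = fit.predict(np.column_stack([np.ones(n), C]))
        ours = 1 / (1 + np.exp(-(params.beta0 + C @ params.beta)))
        np.testing.assert_allclose(ours, reference, atol=1e-4)


class TestTrainLoop:
    @pytest.fixture
    def easy_stack(self):
        design = SimulationDesign(
            n_signal=2, n_nonsignal=4, n_studies=2, n_samples=40, sigma=0.01, seed=3
        )
        stack, _ = generate_stack(design, rng=np.random.default_rng(3))
        return stack

    def test_huge_penalty_shrinks_every_coefficient(self, easy_stack):
        hyper = Hyperparams(lam=1e3, epochs=200)
        state = train(easy_stack, hyper)
        assert np.all(np.abs(state.params.beta) < hyper.select_eps)

    def test_loss_decreases_on_separable_data(self, easy_stack):
        hyper = Hyperparams(lam=0.0, epochs=100)
        state = train(easy_stack, hyper)
        assert state.loss_history[-1] < state.loss_history[0]

    def test_training_is_deterministic(self, easy_stack):
        hyper = Hyperparams(lam=0.01, epochs=50)
        s1 = train(easy_stack, hyper)
        s2 = train(easy_stack, hyper)
        assert s1.loss_history == s2.loss_history
        np.testing.assert_array_equal(s1.params.beta, s2.params.beta)

    def test_loss_history_length_tracks_epochs(self, easy_stack):
        state = train(easy_stack, Hyperparams(lam=0.01, epochs=30))
        assert len(state.loss_history) == state.epoch + 1

    def test_compiled_loop_matches_modular_updates(self, rng):
        """The fused training kernel reproduces the trajectory of the
        modular per-operation updates."""
        from consonet.training import update_v, update_w

        design = SimulationDesign(
            n_signal=3, n_nonsignal=5, n_studies=2, n_samples=30, sigma=0.5, seed=8
        )
        stack, _ = generate_stack(design, rng=np.random.default_rng(8))
        hyper = Hyperparams(lam=0.02, epochs=25, tol=1e-12)

        state = train(stack, hyper)

        params = init_params(stack, hyper)
        cache = forward(stack, params)
        history = [penalized_loss(cache.f, stack.labels, params, hyper.lam)]
        for _ in range(hyper.epochs):
            params = update_beta(cache, stack.labels, params, hyper)
            cache = forward(stack, params)
            params = update_beta0(cache, stack.labels, params, hyper)
            cache = forward(stack, params)
            params = update_w(cache, stack.labels, params, hyper)
            cache = forward(stack, params)
            params = update_v(cache, stack, stack.labels, params, hyper)
            cache = forward(stack, params)
            history.append(penalized_loss(cache.f, stack.labels, params, hyper.lam))

        np.testing.assert_allclose(state.loss_history, history, rtol=1e-9)
        np.testing.assert_allclose(state.params.beta, params.beta, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(state.params.w, params.w, rtol=1e-8)
        np.testing.assert_allclose(state.params.v, params.v, rtol=1e-8)

    def test_warm_start_is_used(self, easy_stack):
        hyper = Hyperparams(lam=0.01, epochs=5)
        first = train(easy_stack, hyper)
        warm = train(easy_stack, hyper, init=first.params)
        assert warm.loss_history[0] == pytest.approx(first.loss_history[-1], rel=1e-6)
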