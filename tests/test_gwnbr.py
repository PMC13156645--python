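import dataclasses
import math

import numpy as np
import pytest
from scipy import optimize

from gwnbr.glm import fit_negbin, nb_loglik
from gwnbr.gwnbr import (
    _grad_hess,
    fit_gwnbr,
    hat_trace,
    local_newton_raphson,
    local_weighted_loglik,
    profile_local_theta,
    restricted_local_loglik,
)
from gwnbr.kernels import KernelSpec, build_kernel_weights, euclidean_distance_matrix
from gwnbr.simulate import default_scenario, generate

from conftest import constant_surface_spec


@pytest.fixture(scope="module")
def n50_data():
    return generate(dataclasses.replace(default_scenario(), n=50))


def _xy(dataset):
    return dataset.design_matrix(), dataset.response.astype(float)


class TestLocalWeightedLoglik:
    def test_unit_weights_reduce_to_global(self, small_dataset):
        X, y = _xy(small_dataset)
        beta = np.array([0.4, 0.2, 0.5])
        ours = local_weighted_loglik(beta, 0.4, X, y, np.ones(len(y)))
        assert ours == pytest.approx(nb_loglik(y, np.exp(X @ beta), 0.4), abs=1e-12)

    def test_linear_in_weights(self, small_dataset):
        X, y = _xy(small_dataset)
        beta = np.array([0.4, 0.2, 0.5])
        full = local_weighted_loglik(beta, 0.4, X, y, np.ones(len(y)))
        half = local_weighted_loglik(beta, 0.4, X, y, 0.5 * np.ones(len(y)))
        assert half == pytest.approx(0.5 * full, abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        y = np.array([2.0, 0.0, 5.0])
        X = np.array([[1.0, 0.3], [1.0, -0.5], [1.0, 1.1]])
        w = np.array([0.9, 0.2, 0.6])
        beta = np.array([0.7, 0.4])
        theta = 0.35
        expect = sum(
            wi * nb_loglik([yi], [math.exp(xi @ beta)], theta)
            for wi, yi, xi in zip(w, y, X)
        )
        assert local_weighted_loglik(beta, theta, X, y, w) == pytest.approx(
            expect, abs=1e-12
        )

    def test_degenerate_weights_rejected(self, small_dataset):
        X, y = _xy(small_dataset)
        w = np.zeros(len(y))
        w[:2] = 1.0  # fewer than p+2 positive weights
        with pytest.raises(ValueError, match="degenerate"):
            local_weighted_loglik(np.zeros(3), 0.4, X, y, w)


class TestDerivatives:
    def test_gradient_and_hessian_match_finite_differences(self, small_dataset):
        X, y = _xy(small_dataset)
        rng = np.random.default_rng(21)
        w = rng.uniform(0.1, 1.0, len(y))
        beta = np.array([0.5, 0.15, 0.6])
        theta = 0.3
        g, H, _ = _grad_hess(beta, theta, X, y, w)
        eps = 1e-6
        for k in range(3):
            step = np.zeros(3)
            step[k] = eps
            num_g = (
                local_weighted_loglik(beta + step, theta, X, y, w)
                - local_weighted_loglik(beta - step, theta, X, y, w)
            ) / (2 * eps)
            assert g[k] == pytest.approx(num_g, rel=1e-5)
            gp, _, _ = _grad_hess(beta + step, theta, X, y, w)
            gm, _, _ = _grad_hess(beta - step, theta, X, y, w)
            np.testing.assert_allclose(H[:, k], (gp - gm) / (2 * eps), rtol=1e-4)


class TestLocalNewtonRaphson:
    def test_unit_weights_fixed_point_of_global_fit(self, small_dataset):
        nb = fit_negbin(small_dataset)
        X, y = _xy(small_dataset)
        beta, _, iters, converged = local_newton_raphson(
            X, y, np.ones(len(y)), nb.coefficients, nb.theta
        )
        assert converged and iters <= 2
        np.testing.assert_allclose(beta, nb.coefficients, atol=1e-6)

    def test_poisson_limit_matches_grid_search(self):
        """Near theta=0 with one covariate the maximizer matches a dense scan."""
        rng = np.random.default_rng(31)
        n = 10
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(0.8 * x)).astype(float)
        X = x[:, None]
        w = rng.uniform(0.5, 1.0, n)
        beta, _, _, converged = local_newton_raphson(
            X, y, w, np.array([0.0]), 1e-8, max_iterations=50
        )
        assert converged
        grid = np.linspace(-2, 2, 40001)
        lls = [local_weighted_loglik(np.array([b]), 1e-8, X, y, w) for b in grid]
        assert beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_loglik_nondecreasing_over_iterations(self, small_dataset):
        X, y = _xy(small_dataset)
        rng = np.random.default_rng(41)
        w = rng.uniform(0.05, 1.0, len(y))
        start = np.array([math.log(y.mean()), 0.0, 0.0])
        lls = []
        beta = start
        for it in range(1, 9):
            b, _, _, _ = local_newton_raphson(X, y, w, start, 0.3, max_iterations=it)
            lls.append(local_weighted_loglik(b, 0.3, X, y, w))
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_underdetermined_weights_error(self, small_dataset):
        X, y = _xy(small_dataset)
        w = np.zeros(len(y))
        w[:3] = 1.0  # exactly p+1 points: underdetermined by our margin rule
        with pytest.raises(ValueError, match="degenerate"):
            local_newton_raphson(X, y, w, np.zeros(3), 0.3)


class TestProfileLocalTheta:
    def test_locally_poisson_data_hits_floor(self, poisson_spec):
        ds, _ = generate(dataclasses.replace(poisson_spec, n=80))
        X, y = _xy(ds)
        w = np.ones(len(y))
        beta0 = np.array([math.log(y.mean()), 0, 0, 0, 0.0])
        beta, _, _, _ = local_newton_raphson(X, y, w, beta0, 1e-4, max_iterations=50)
        theta, _, _, _ = profile_local_theta(X, y, w, beta)
        assert theta <= 0.01

    def test_argmax_property(self, small_dataset):
        X, y = _xy(small_dataset)
        rng = np.random.default_rng(51)
        w = rng.uniform(0.2, 1.0, len(y))
        nb = fit_negbin(small_dataset)
        theta, beta, _, _ = profile_local_theta(X, y, w, nb.coefficients)
        best = local_weighted_loglik(beta, theta, X, y, w)
        for alt in np.logspace(-8, 4, 21):
            assert best >= local_weighted_loglik(beta, alt, X, y, w) - 1e-8

    def test_theta_recovery_wide_bandwidth(self):
        spec = constant_surface_spec(n=300, theta=0.5, seed=99)
        ds, _ = generate(spec)
        X, y = _xy(ds)
        w = np.ones(len(y))
        beta0 = fit_negbin(ds).coefficients
        theta, _, _, _ = profile_local_theta(X, y, w, beta0)
        assert 0.25 <= theta <= 0.9


class TestHatTrace:
    def test_global_limit_equals_parameter_count(self, small_dataset):
        nb = fit_negbin(small_dataset)
        X, _ = _xy(small_dataset)
        n, k = X.shape
        B = np.tile(nb.coefficients, (n, 1))
        tr = hat_trace(X, np.ones((n, n)), B, np.full(n, nb.theta))
        assert tr == pytest.approx(k, abs=1e-3)

    def test_leverages_match_explicit_hat_row(self):
        """s_ii equals element i of the explicitly built hat-matrix row."""
        rng = np.random.default_rng(61)
        n, k = 8, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        W = rng.uniform(0.2, 1.0, size=(n, n))
        np.fill_diagonal(W, 1.0)
        B = np.tile([0.5, 0.2, -0.1], (n, 1)) + 0.05 * rng.normal(size=(n, k))
        thetas = rng.uniform(0.05, 0.5, n)
        from gwnbr.gwnbr import _leverages

        lev = _leverages(X, W, B, thetas)
        for i in range(n):
            mu = np.exp(X @ B[i])
            v = mu / (1 + thetas[i] * mu)
            A = np.diag(W[i] * v)
            S_row = X[i] @ np.linalg.inv(X.T @ A @ X) @ X.T @ A
            assert lev[i] == pytest.approx(S_row[i], abs=1e-10)

    def test_leverage_bounds(self, n50_data):
        ds, _ = n50_data
        D = euclidean_distance_matrix(ds.coords)
        kw = build_kernel_weights(D, KernelSpec("bisquare", "adaptive", 0.6),
                                  min_positive=ds.p + 2)
        fit = fit_gwnbr(ds, kw)
        lev = np.array([lf.leverage for lf in fit.local_fits])
        assert np.all(lev > 0) and np.all(lev <= 1 + 1e-10)


class TestFitGWNBR:
    def test_global_limit_reproduces_global_nb(self, n50_data):
        ds, _ = n50_data
        nb = fit_negbin(ds)
        D = euclidean_distance_matrix(ds.coords)
        kw = build_kernel_weights(D, KernelSpec("gaussian", "fixed", 1e9),
                                  min_positive=ds.p + 2)
        fit = fit_gwnbr(ds, kw, global_fit=nb)
        assert np.abs(fit.coefficients - nb.coefficients).max() < 1e-4
        assert fit.trace_S == pytest.approx(ds.p + 1, abs=0.05)

    def test_surface_recovery(self):
        # n=100 keeps the local noise floor well under the surface's spread
        ds, truth = generate(dataclasses.replace(default_scenario(), n=100))
        D = euclidean_distance_matrix(ds.coords)
        kw = build_kernel_weights(D, KernelSpec("bisquare", "adaptive", 0.6),
                                  min_positive=ds.p + 2)
        fit = fit_gwnbr(ds, kw)
        r = np.corrcoef(fit.coefficients[:, 1], truth["surfaces"][:, 1])[0, 1]
        assert r >= 0.8

    def test_permutation_equivariance(self, small_dataset):
        D = euclidean_distance_matrix(small_dataset.coords)
        kw = build_kernel_weights(D, KernelSpec("gaussian", "fixed", 6.0),
                                  min_positive=4)
        fit = fit_gwnbr(small_dataset, kw)
        rng = np.random.default_rng(71)
        perm = rng.permutation(small_dataset.n)
        shuffled = dataclasses.replace(
            small_dataset,
            unit_labels=tuple(small_dataset.unit_labels[i] for i in perm),
            response=small_dataset.response[perm],
            covariates=small_dataset.covariates[perm],
            coords=small_dataset.coords[perm],
        )
        D2 = euclidean_distance_matrix(shuffled.coords)
        kw2 = build_kernel_weights(D2, KernelSpec("gaussian", "fixed", 6.0),
                                   min_positive=4)
        fit2 = fit_gwnbr(shuffled, kw2)
        np.testing.assert_allclose(fit2.coefficients, fit.coefficients[perm],
                                   atol=1e-6)
        assert fit2.trace_S == pytest.approx(fit.trace_S, abs=1e-6)

    def test_aic_identity_and_effective_df(self, small_dataset):
        D = euclidean_distance_matrix(small_dataset.coords)
        kw = build_kernel_weights(D, KernelSpec("gaussian", "fixed", 6.0),
                                  min_positive=4)
        fit = fit_gwnbr(small_dataset, kw)
        assert fit.aic == pytest.approx(
            -2 * fit.log_likelihood + 2 * (fit.trace_S + 1), rel=1e-12
        )
        assert fit.effective_df == pytest.approx(small_dataset.n - fit.trace_S)
        assert 0 < fit.trace_S < small_dataset.n
        assert np.all(fit.fitted_means > 0)

    def test_restricted_model_never_beats_full(self, small_dataset):
        D = euclidean_distance_matrix(small_dataset.coords)
        kw = build_kernel_weights(D, KernelSpec("gaussian", "fixed", 6.0),
                                  min_positive=4)
        fit = fit_gwnbr(small_dataset, kw)
        restricted = restricted_local_loglik(small_dataset, kw)
        assert fit.log_likelihood >= restricted - 1e-6
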