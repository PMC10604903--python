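"""Penalized fitting: descent, sparsity path, oracle reductions, null fits."""

import numpy as np
import pytest
import scipy.optimize

from regmtlmm import (CovariancePair, FitOptions, PenaltySpec,
                      eigendecompose_kinship, fit_regularized_mtlmm,
                      fit_univariate_ml, fit_variance_components_null,
                      gls_effects, rotate, select_regularization)
from regmtlmm.estimation import _init_cov, lambda_max

from conftest import dense_nll, labeled_dataset, random_instance

FAST = FitOptions(outer_max=15, fista_max=300)


@pytest.fixture(scope="module")
def tiny_data():
    rng = np.random.default_rng(5)
    n, q, p = 30, 2, 3
    A = rng.standard_normal((n, n))
    K = A @ A.T / n
    X = rng.standard_normal((n, p))
    B_true = np.array([[1.0, 0.0], [0.0, -1.0], [0.5, 0.5]])
    Lk = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    Y = X @ B_true + 0.6 * Lk @ rng.standard_normal((n, q)) \
        + 0.4 * rng.standard_normal((n, q))
    return labeled_dataset(K, Y, X)


class TestRegularizedFit:
    def test_objective_trace_non_increasing(self, tiny_data):
        fit = fit_regularized_mtlmm(tiny_data, PenaltySpec(lam=1.0, gamma=0.5),
                                    FAST)
        trace = np.asarray(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_lambda_above_lambda_max_gives_zero(self, tiny_data):
        eig = eigendecompose_kinship(tiny_data.kinship)
        rot = rotate(eig, tiny_data.traits, tiny_data.genotypes)
        lmax = lambda_max(rot, _init_cov(tiny_data.traits.values))
        fit = fit_regularized_mtlmm(tiny_data, PenaltySpec(lam=2.0 * lmax),
                                    FAST)
        assert np.all(fit.B_hat.values == 0.0)
        assert np.all(np.isfinite(fit.intercept))

    def test_sparsity_non_increasing_along_lambda_path(self, tiny_data):
        eig = eigendecompose_kinship(tiny_data.kinship)
        rot = rotate(eig, tiny_data.traits, tiny_data.genotypes)
        lmax = lambda_max(rot, _init_cov(tiny_data.traits.values))
        counts = []
        for frac in (0.02, 0.1, 0.3, 0.7, 1.2):
            fit = fit_regularized_mtlmm(tiny_data, PenaltySpec(lam=frac * lmax),
                                        FAST)
            counts.append(int(fit.support.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_unpenalized_fit_matches_gls_ml_oracle(self, tiny_data):
        """lam = gamma = 0, p < n: alternating exact GLS + generic
        covariance optimization on the dense likelihood is the oracle."""
        fit = fit_regularized_mtlmm(tiny_data, PenaltySpec(),
                                    FitOptions(outer_max=60, fista_max=800,
                                               fista_tol=1e-10,
                                               outer_tol=1e-12,
                                               cov_maxiter=400))
        Y = tiny_data.traits.values
        X = tiny_data.genotypes.values
        K = tiny_data.kinship.values
        n, q = Y.shape
        eig = eigendecompose_kinship(tiny_data.kinship)
        rot = rotate(eig, tiny_data.traits, tiny_data.genotypes)

        # oracle: profile likelihood — exact GLS for (B, mu) inside a
        # generic optimizer over the covariance parameters, evaluated with
        # the dense Kronecker likelihood
        def unpack(params):
            Lg = np.zeros((q, q))
            Le = np.zeros((q, q))
            Lg[np.tril_indices(q)] = params[:3]
            Le[np.tril_indices(q)] = params[3:]
            return CovariancePair(Lg @ Lg.T, Le @ Le.T + 1e-8 * np.eye(q))

        def profile_obj(pp):
            try:
                cov = unpack(pp)
                B, mu, _ = gls_effects(rot, cov, return_cov=False)
                return dense_nll(Y, X, B, K, cov, intercept=mu)
            except np.linalg.LinAlgError:
                return 1e30

        cov0 = _init_cov(Y)
        x0 = np.array([np.sqrt(cov0.Cg[0, 0]), 0.0, np.sqrt(cov0.Cg[1, 1])] * 2)
        res = scipy.optimize.minimize(profile_obj, x0, method="Nelder-Mead",
                                      options={"maxiter": 4000,
                                               "fatol": 1e-13,
                                               "xatol": 1e-10})
        B, mu, _ = gls_effects(rot, unpack(res.x), return_cov=False)
        oracle_obj = float(res.fun)
        np.testing.assert_allclose(fit.B_hat.values, B, atol=1e-5)
        assert fit.objective_trace[-1] <= oracle_obj + 1e-6

    def test_mtlm_q1_matches_sklearn_lasso(self):
        from sklearn.linear_model import Lasso
        rng = np.random.default_rng(11)
        n, p = 40, 6
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        y = X[:, 0] - 0.8 * X[:, 3] + 0.3 * rng.standard_normal(n)
        data = labeled_dataset(np.eye(n), y[:, None], X)
        lam = 8.0
        fit = fit_regularized_mtlmm(data, PenaltySpec(lam=lam),
                                    FitOptions(outer_max=40, fista_max=2000,
                                               fista_tol=1e-12,
                                               outer_tol=1e-10),
                                    model="mtLM")
        sigma2 = fit.cov_hat.Ce[0, 0]
        # minimizing RSS/(2 sigma2) + lam * ||b||_1 is the lasso with
        # alpha = lam * sigma2 / n on sklearn's 1/(2n) RSS scale
        model = Lasso(alpha=lam * sigma2 / n, fit_intercept=True,
                      tol=1e-12, max_iter=100000)
        model.fit(X, y)
        np.testing.assert_allclose(fit.B_hat.values[:, 0], model.coef_,
                                   atol=1e-5)

    def test_mtlm_ignores_kinship(self, tiny_data, rng):
        """With Cg frozen at zero the kinship drops out of the model."""
        tight = FitOptions(outer_max=40, fista_max=3000, fista_tol=1e-12,
                           outer_tol=1e-10)
        fit1 = fit_regularized_mtlmm(tiny_data, PenaltySpec(lam=0.5), tight,
                                     model="mtLM")
        other = labeled_dataset(np.eye(tiny_data.n),
                                tiny_data.traits.values,
                                tiny_data.genotypes.values)
        fit2 = fit_regularized_mtlmm(other, PenaltySpec(lam=0.5), tight,
                                     model="mtLM")
        np.testing.assert_allclose(fit1.B_hat.values, fit2.B_hat.values,
                                   atol=1e-4)
        np.testing.assert_allclose(fit1.cov_hat.Ce, fit2.cov_hat.Ce, atol=1e-4)

    def test_trait_permutation_equivariance(self, tiny_data):
        tight = FitOptions(outer_max=40, fista_max=3000, fista_tol=1e-12,
                           outer_tol=1e-10)
        fit = fit_regularized_mtlmm(tiny_data, PenaltySpec(lam=1.0), tight)
        perm = [1, 0]
        swapped = labeled_dataset(tiny_data.kinship.values,
                                  tiny_data.traits.values[:, perm],
                                  tiny_data.genotypes.values)
        fit_p = fit_regularized_mtlmm(swapped, PenaltySpec(lam=1.0), tight)
        np.testing.assert_allclose(fit_p.B_hat.values,
                                   fit.B_hat.values[:, perm], atol=1e-4)


class TestNullVarianceComponents:
    def test_q1_matches_dense_scalar_oracle(self):
        rng = np.random.default_rng(17)
        n = 120
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        Lk = np.linalg.cholesky(K + 1e-9 * np.eye(n))
        y = 1.5 + 0.9 * Lk @ rng.standard_normal(n) + 0.7 * rng.standard_normal(n)
        data = labeled_dataset(K, y[:, None], rng.standard_normal((n, 1)))
        cov = fit_variance_components_null(data)

        def oracle(params):
            sg2, se2 = np.exp(params)
            S = sg2 * K + se2 * np.eye(n)
            sign, logdet = np.linalg.slogdet(S)
            Si = np.linalg.inv(S)
            one = np.ones(n)
            mu = (one @ Si @ y) / (one @ Si @ one)
            r = y - mu
            return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ Si @ r)

        res = scipy.optimize.minimize(oracle, np.log([0.5, 0.5]),
                                      method="Nelder-Mead",
                                      options={"fatol": 1e-12, "xatol": 1e-10})
        sg2, se2 = np.exp(res.x)
        assert cov.Cg[0, 0] == pytest.approx(sg2, abs=1e-4, rel=1e-3)
        assert cov.Ce[0, 0] == pytest.approx(se2, abs=1e-4, rel=1e-3)

    def test_identity_kinship_forces_cg_zero(self, rng):
        n = 30
        Y = rng.standard_normal((n, 2))
        data = labeled_dataset(np.eye(n), Y, rng.standard_normal((n, 2)))
        with pytest.warns(UserWarning, match="identifiable"):
            cov = fit_variance_components_null(data)
        np.testing.assert_array_equal(cov.Cg, 0.0)

    def test_zero_variance_phenotype_rejected(self, rng):
        n = 10
        A = rng.standard_normal((n, n))
        data = labeled_dataset(A @ A.T, np.ones((n, 1)),
                               rng.standard_normal((n, 2)))
        with pytest.raises(ValueError, match="zero variance"):
            fit_variance_components_null(data)


class TestUnivariateML:
    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(3)
        n = 60
        s = np.sort(rng.uniform(0, 3, n))[::-1]
        y = np.sqrt(0.7 * s + 0.5) * rng.standard_normal(n)
        D = np.ones((n, 1))
        sg2, se2, _, nll = fit_univariate_ml(s, y, D)

        def dense(sg2_, se2_):
            v = sg2_ * s + se2_
            mu = np.sum(y / v) / np.sum(1.0 / v)
            r = y - mu
            return 0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(v))
                          + np.sum(r * r / v))

        # profile fit should beat every point of a dense 2-D grid
        grid = np.linspace(0.01, 3.0, 40)
        best = min(dense(a, b) for a in grid for b in grid)
        assert nll <= best + 1e-6
        assert abs(dense(sg2, se2) - nll) < 1e-8


class TestSelectRegularization:
    def test_single_spec_grid_returned(self, small_dataset):
        data, _, _ = small_dataset
        spec = PenaltySpec(lam=1.0)
        best, table = select_regularization(data, [spec], FAST, seed=1)
        assert best == spec.resolve(data.q)
        assert len(table) == 1

    def test_tie_break_prefers_stronger_regularization(self, small_dataset):
        data, _, _ = small_dataset
        eig = eigendecompose_kinship(data.kinship)
        rot = rotate(eig, data.traits, data.genotypes)
        lmax = lambda_max(rot, _init_cov(data.traits.values))
        # both specs are above lambda_max -> identical (all-zero) fits
        g1, g2 = PenaltySpec(lam=2.0 * lmax), PenaltySpec(lam=3.0 * lmax)
        best, table = select_regularization(data, [g1, g2], FAST, seed=1)
        assert best.lam == pytest.approx(3.0 * lmax)

    def test_planted_optimum_wins(self):
        rng = np.random.default_rng(23)
        n, p, q = 50, 8, 2
        X = rng.standard_normal((n, p))
        B = np.zeros((p, q))
        B[0, 0] = 2.0
        B[3, 1] = -1.5
        Y = X @ B + 0.01 * rng.standard_normal((n, q))
        A = rng.standard_normal((n, n))
        data = labeled_dataset(A @ A.T / n, Y, X)
        good = PenaltySpec(lam=0.05)
        bad = PenaltySpec(lam=1e4)
        best, table = select_regularization(data, [bad, good], FAST, seed=2)
        assert best.lam == pytest.approx(0.05)
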