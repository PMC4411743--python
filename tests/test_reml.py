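"""REML machinery: likelihood values, AI fits, LRTs, transforms."""

import numpy as np
import pytest
from scipy import optimize, stats

from gxekit.reml import (
    RemlError,
    VarianceComponentsREML,
    fit_univariate,
    lrt_component,
    reml_loglik,
    transform_phenotype,
)


def dense_restricted_loglik(y, X, V):
    """Independent dense-algebra oracle using explicit inverses and
    determinants (no Cholesky shortcuts)."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(y @ P @ y)
    )


def random_fixture(seed, n=50, m=120):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    A = Z @ Z.T / m
    e = rng.binomial(1, 0.5, n).astype(float)
    Age = np.where(e[:, None] == e[None, :], A, 0.0)
    X = np.column_stack([np.ones(n), e])
    y = rng.normal(size=n)
    return y, X, A, Age


class TestRemlLoglik:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_dense_oracle(self, seed):
        y, X, A, Age = random_fixture(seed)
        sig = [0.3, 0.2, 0.6]
        ours = reml_loglik(y, [A, Age], sig, X=X)
        V = sig[0] * A + sig[1] * Age + sig[2] * np.eye(y.size)
        assert ours == pytest.approx(dense_restricted_loglik(y, X, V), abs=1e-8)

    def test_zero_matrix_component_is_inert(self):
        y, X, A, _ = random_fixture(4)
        zero = np.zeros((y.size, y.size))
        l1 = reml_loglik(y, [A, zero], [0.5, 0.1, 0.5], X=X)
        l2 = reml_loglik(y, [A, zero], [0.5, 99.0, 0.5], X=X)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_translation_invariance_with_intercept(self):
        y, X, A, _ = random_fixture(5)
        l1 = reml_loglik(y, [A], [0.4, 0.6], X=X)
        l2 = reml_loglik(y + 7.3, [A], [0.4, 0.6], X=X)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_singular_v_reports_eigenvalue(self):
        y, X, A, _ = random_fixture(6)
        with pytest.raises(RemlError, match="eigenvalue"):
            reml_loglik(y, [A], [-50.0, 0.0], X=X)


class TestFitUnivariate:
    def test_matches_brute_force_surface(self):
        y, X, A, Age = random_fixture(7, n=150, m=200)
        rng = np.random.default_rng(7)
        L = np.linalg.cholesky(0.4 * A + 0.2 * Age + 0.4 * np.eye(150) + 1e-10 * np.eye(150))
        y = L @ rng.normal(size=150)
        fit = fit_univariate(y, [A, Age], X=X)
        best = -np.inf
        arg = None
        grid = np.linspace(0.02, 1.2, 6) * y.var()
        for a in grid:
            for b in grid:
                for c in grid:
                    ll = reml_loglik(y, [A, Age], [a, b, c], X=X)
                    if ll > best:
                        best, arg = ll, (a, b, c)
        res = optimize.minimize(
            lambda t: -reml_loglik(y, [A, Age], np.maximum(t, 1e-9), X=X),
            arg,
            method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-12, maxiter=3000),
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_identity_component_aliasing_rejected(self, rng):
        y = rng.normal(size=60)
        with pytest.raises(ValueError, match="proportional"):
            fit_univariate(y, [np.eye(60)], X=np.ones((60, 1)))

    def test_scaling_phenotype_scales_components(self):
        y, X, A, Age = random_fixture(8, n=120, m=150)
        f1 = fit_univariate(y, [A, Age], X=X)
        f2 = fit_univariate(3.0 * y, [A, Age], X=X)
        np.testing.assert_allclose(f2.estimates, 9.0 * f1.estimates, rtol=1e-4, atol=1e-8)
        np.testing.assert_allclose(f2.proportions, f1.proportions, atol=1e-6)
        # LRT against the genetic-only reduced model is scale-free
        r1 = fit_univariate(y, [A], X=X)
        r2 = fit_univariate(3.0 * y, [A], X=X)
        t1 = lrt_component(f1, r1)
        t2 = lrt_component(f2, r2)
        assert t1.statistic == pytest.approx(t2.statistic, abs=1e-5)

    def test_proportions_sum_to_one_and_se_finite(self):
        y, X, A, Age = random_fixture(9, n=100)
        fit = fit_univariate(y, [A, Age], X=X)
        assert fit.proportions.sum() == pytest.approx(1.0)
        assert np.isfinite(fit.se).all()
        assert fit.converged and len(fit.trace) == fit.n_iter

    def test_unconstrained_fit_allows_negative(self):
        # a phenotype with *less* genetic structure than the residual can
        # push the unconstrained genetic component below zero
        rng = np.random.default_rng(10)
        n = 80
        Z = rng.normal(size=(n, 30))
        A = Z @ Z.T / 30
        y = rng.normal(size=n)
        est = VarianceComponentsREML(constrain=False).fit([A], y)
        assert est.converged_
        # constrained fit stays at the floor instead
        est_c = VarianceComponentsREML(constrain=True).fit([A], y)
        assert (est_c.estimates_ >= 0).all()

    def test_too_few_observations_rejected(self, rng):
        y = rng.normal(size=8)
        with pytest.raises(ValueError, match="too few"):
            fit_univariate(y, [np.eye(8) * 0.5 + 0.5], X=np.ones((8, 1)))


class TestLrt:
    def test_identical_fits_give_p_one(self):
        r = lrt_component(-10.0, -10.0, boundary=True)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_chi2_quantile(self):
        r = lrt_component(0.0, -1.92, df=1, boundary=False)
        assert r.statistic == pytest.approx(3.84)
        assert r.p_value == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-12)
        assert r.p_value == pytest.approx(0.050, abs=5e-4)

    def test_boundary_mixture_halves_p(self):
        plain = lrt_component(0.0, -1.92, boundary=False)
        mix = lrt_component(0.0, -1.92, boundary=True)
        assert mix.p_value == pytest.approx(plain.p_value / 2)

    def test_reduced_better_than_full_errors(self):
        with pytest.raises(RemlError, match="exceeds"):
            lrt_component(-10.0, -5.0)


class TestTransformPhenotype:
    def test_rank_inverse_normal_monotone_invariant(self, rng):
        y = rng.gamma(2.0, size=500)
        np.testing.assert_allclose(
            transform_phenotype(y, "rank-inverse-normal"),
            transform_phenotype(np.exp(y), "rank-inverse-normal"),
        )

    def test_rank_inverse_normal_tracks_normal_input(self, rng):
        y = rng.normal(size=2000)
        z = transform_phenotype(y, "rank-inverse-normal")
        assert np.corrcoef(y, z)[0, 1] > 0.99

    def test_log_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            transform_phenotype(np.array([1.0, -1.0]), "log")
        np.testing.assert_allclose(
            transform_phenotype(np.array([1.0, np.e]), "log"), [0.0, 1.0]
        )

    def test_none_is_identity(self, rng):
        y = rng.normal(size=10)
        np.testing.assert_array_equal(transform_phenotype(y, "none"), y)
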