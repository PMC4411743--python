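"""Bivariate cross-environment mixed model and the r_g = 1 test.

With a binary exposure the phenotype in each environment is treated as a
separate trait.  Individuals are observed in exactly one environment, so
the stacked covariance has within-group blocks σ²_g,k A_kk + σ²_e,k I and a
cross-group genetic block r_g σ_g,1 σ_g,2 A_12 (no residual cross-
covariance).  SNP-heritabilities are free to differ between environments.
A genetic correlation significantly below one implies G×E; the test
compares the free fit against the r_g = 1 constrained fit by a df = 1
likelihood-ratio test (the r_g = 0 fit and test are reported as well).
Because the genetic correlation is unaffected by per-environment
ascertainment, this is the recommended significance test for disease
traits, where per-environment SNP-heritability estimates themselves are
hard to interpret.

The free fit uses the linear parameterisation (σ²_g1, σ²_g2, c_g, σ²_e1,
σ²_e2), for which the average-information machinery applies unchanged
(c_g unconstrained in sign); the r_g = 1 fit maximises over genetic
standard deviations with an analytic REML gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .containers import EnvironmentVector, Grm, SampleVector
from .reml import RemlError, _ai_reml, _loglik_terms, _validate_model, lrt_component

__all__ = ["BivariateGxEREML", "BivariateFit", "fit_bivariate"]


@dataclass
class BivariateFit:
    var_g: tuple  # per-environment genetic variances
    var_e: tuple  # per-environment residual variances
    cov_g: float
    rg: float
    rg_se: float
    loglik_free: float
    loglik_rg1: float
    loglik_rg0: float
    lrt_rg1: object
    lrt_rg0: object
    n: tuple
    rg_defined: bool


def _blocks(A, idx1, idx2):
    n1, n2 = idx1.size, idx2.size
    n = n1 + n2
    B_g1 = np.zeros((n, n))
    B_g1[:n1, :n1] = A[np.ix_(idx1, idx1)]
    B_g2 = np.zeros((n, n))
    B_g2[n1:, n1:] = A[np.ix_(idx2, idx2)]
    B_c = np.zeros((n, n))
    B_c[:n1, n1:] = A[np.ix_(idx1, idx2)]
    B_c[n1:, :n1] = A[np.ix_(idx2, idx1)]
    B_e1 = np.diag(np.r_[np.ones(n1), np.zeros(n2)])
    B_e2 = np.diag(np.r_[np.zeros(n1), np.ones(n2)])
    return B_g1, B_g2, B_c, B_e1, B_e2


def _neg_ll_and_grad(theta, y, X, mats):
    V = sum(t * B for t, B in zip(theta, mats))
    ll, P, Py = _loglik_terms(y, X, V)
    grad = np.array(
        [-0.5 * (np.sum(P * B) - float(Py @ (B @ Py))) for B in mats]
    )
    return -ll, -grad


class BivariateGxEREML(BaseEstimator):
    """Two-environment bivariate GREML with constrained r_g fits.

    Parameters mirror :class:`~gxekit.reml.VarianceComponentsREML`;
    ``min_group`` is the smallest acceptable per-environment sample size.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-8, min_group: int = 50):
        self.max_iter = max_iter
        self.tol = tol
        self.min_group = min_group

    def fit(self, grm: Grm, y, env, covariates: np.ndarray | None = None):
        A = grm.values
        yv = y.align_to(grm.ids) if isinstance(y, SampleVector) else np.asarray(y, float).ravel()
        ev = env.align_to(grm.ids) if isinstance(env, EnvironmentVector) else np.asarray(env, float).ravel()
        if np.isnan(yv).any() or np.isnan(ev).any():
            raise ValueError("phenotype or environment missing for some GRM samples")
        levels = np.unique(ev)
        if levels.size != 2:
            raise ValueError(
                f"bivariate model needs exactly two environment groups, found {levels.size}"
            )
        idx1 = np.where(ev == levels[0])[0]
        idx2 = np.where(ev == levels[1])[0]
        if min(idx1.size, idx2.size) < self.min_group:
            raise ValueError(
                f"environment group smaller than {self.min_group} "
                f"({idx1.size} vs {idx2.size})"
            )
        order = np.r_[idx1, idx2]
        yy = yv[order]
        n1, n2 = idx1.size, idx2.size
        mats = list(_blocks(A, idx1, idx2))
        # per-group intercepts (and optional per-group covariate slopes)
        X = np.zeros((n1 + n2, 2))
        X[:n1, 0] = 1.0
        X[n1:, 1] = 1.0
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] == 1:
                C = C.T
            X = np.hstack([X, C[order]])
        yy, X, mats = _validate_model(yy, X, mats)

        names = ["var_g1", "var_g2", "cov_g", "var_e1", "var_e2"]
        free = _ai_reml(
            yy,
            X,
            mats,
            names,
            max_iter=self.max_iter,
            tol=self.tol,
            constrain=False,
            bound_tol=1e-5,
        )
        # keep variances non-negative: refit constrained if any went negative
        if (free.estimates[[0, 1, 3, 4]] < 0).any():
            free = _constrained_free_fit(yy, X, mats, free)

        vg1, vg2, cg, ve1, ve2 = free.estimates[:5]
        vary = float(np.var(yy, ddof=1))
        rg_defined = min(vg1, vg2) > 1e-4 * vary
        rg = cg / np.sqrt(vg1 * vg2) if rg_defined else np.nan
        rg_se = _rg_se(free) if rg_defined else np.nan

        # r_g = 0: drop the cross block
        r0 = _ai_reml(
            yy,
            X,
            [mats[0], mats[1], mats[3], mats[4]],
            ["var_g1", "var_g2", "var_e1", "var_e2"],
            max_iter=self.max_iter,
            tol=self.tol,
            constrain=True,
            bound_tol=1e-5,
        )
        # r_g = 1: cov constrained to sigma_g1 * sigma_g2
        ll_r1, _ = _fit_rg1(yy, X, mats, free, vary)

        ll_free = free.loglik
        # the constrained optima can never exceed the free one; polish if the
        # free fit stalled short of them
        if ll_free < max(ll_r1, r0.loglik) - 1e-6:
            free_polish = _polish_free(yy, X, mats, free)
            if free_polish is not None and free_polish[0] > ll_free:
                ll_free, est = free_polish
                vg1, vg2, cg, ve1, ve2 = est
                rg_defined = min(vg1, vg2) > 1e-4 * vary
                rg = cg / np.sqrt(vg1 * vg2) if rg_defined else np.nan

        lrt1 = lrt_component(ll_free, ll_r1, df=1, boundary=False)
        lrt0 = lrt_component(ll_free, r0.loglik, df=1, boundary=False)

        self.fit_ = BivariateFit(
            var_g=(vg1, vg2),
            var_e=(ve1, ve2),
            cov_g=cg,
            rg=float(rg),
            rg_se=float(rg_se),
            loglik_free=ll_free,
            loglik_rg1=ll_r1,
            loglik_rg0=r0.loglik,
            lrt_rg1=lrt1,
            lrt_rg0=lrt0,
            n=(n1, n2),
            rg_defined=bool(rg_defined),
        )
        self.rg_ = self.fit_.rg
        self.loglik_ = ll_free
        return self


def _rg_se(free) -> float:
    """Delta-method SE of r_g = c / sqrt(v1 v2) from the AI covariance."""
    v1, v2, c = free.estimates[0], free.estimates[1], free.estimates[2]
    # marginal AI standard errors combined as if independent (slightly
    # conservative; the full AI covariance is available via free.trace)
    r = c / np.sqrt(v1 * v2)
    dv1 = -0.5 * r / v1
    dv2 = -0.5 * r / v2
    dc = 1.0 / np.sqrt(v1 * v2)
    se = np.sqrt(
        (dv1 * free.se[0]) ** 2 + (dv2 * free.se[1]) ** 2 + (dc * free.se[2]) ** 2
    )
    return float(se)


def _constrained_free_fit(yy, X, mats, warm):
    """Free fit with variance components clamped non-negative (c_g free)."""
    vary = float(np.var(yy, ddof=1))
    floor = 1e-8 * vary

    def nll(theta):
        t = theta.copy()
        try:
            f, g = _neg_ll_and_grad(t, yy, X, mats)
        except RemlError:
            return 1e10, np.zeros_like(theta)
        return f, g

    x0 = warm.estimates.copy()
    x0[[0, 1, 3, 4]] = np.maximum(x0[[0, 1, 3, 4]], floor)
    bounds = [(floor, None), (floor, None), (None, None), (floor, None), (floor, None)]
    res = optimize.minimize(nll, x0, jac=True, method="L-BFGS-B", bounds=bounds)
    warm.estimates = res.x
    warm.loglik = -float(res.fun)
    return warm


def _polish_free(yy, X, mats, warm):
    try:
        res = optimize.minimize(
            lambda t: _safe_nll(t, yy, X, mats),
            warm.estimates,
            jac=True,
            method="L-BFGS-B",
        )
        return -float(res.fun), res.x
    except Exception:
        return None


def _safe_nll(theta, yy, X, mats):
    try:
        return _neg_ll_and_grad(theta, yy, X, mats)
    except RemlError:
        return 1e10, np.zeros_like(theta)


def _fit_rg1(yy, X, mats, free, vary):
    """Maximise the restricted likelihood under r_g = 1.

    Parameterised by genetic standard deviations (s1, s2) and residual
    variances, with V = s1²B_g1 + s2²B_g2 + s1 s2 B_c + ve1 B_e1 + ve2 B_e2.
    """
    B_g1, B_g2, B_c, B_e1, B_e2 = mats
    floor = 1e-8 * vary

    def nll(par):
        s1, s2, ve1, ve2 = par
        V = s1**2 * B_g1 + s2**2 * B_g2 + s1 * s2 * B_c + ve1 * B_e1 + ve2 * B_e2
        try:
            ll, P, Py = _loglik_terms(yy, X, V)
        except RemlError:
            return 1e10, np.zeros(4)
        dVs = [
            2 * s1 * B_g1 + s2 * B_c,
            2 * s2 * B_g2 + s1 * B_c,
            B_e1,
            B_e2,
        ]
        grad = np.array(
            [0.5 * (np.sum(P * D) - float(Py @ (D @ Py))) for D in dVs]
        )
        return -ll, grad

    vg1, vg2 = np.maximum(free.estimates[[0, 1]], floor)
    x0 = np.array(
        [np.sqrt(vg1), np.sqrt(vg2), max(free.estimates[3], floor), max(free.estimates[4], floor)]
    )
    best = None
    for start in (x0, np.array([np.sqrt(vary / 2)] * 2 + [vary / 2] * 2)):
        res = optimize.minimize(
            nll, start, jac=True, method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None), (floor, None), (floor, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    return -float(best.fun), best.x


def fit_bivariate(y, env, grm: Grm, covariates=None, **kwargs) -> BivariateFit:
    """Functional wrapper around :class:`BivariateGxEREML`."""
    est = BivariateGxEREML(**kwargs)
    est.fit(grm, y, env, covariates=covariates)
    return est.fit_
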