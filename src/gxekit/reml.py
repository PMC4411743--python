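"""Restricted maximum likelihood estimation of G and G×E variance components.

Model
-----
y = X b + g + ge + ε with Var(y) = σ²_g A_g + σ²_ge A_ge + σ²_e I: the
phenotypic variance decomposes into a genetic part spread through the
genetic relationship matrix, an interaction part spread through the
environment-masked (or reaction-norm) relationship matrix, and residual
noise.  Components are estimated by average-information REML with EM
fallback steps, constrained to be non-negative by default.  Component
significance is tested by likelihood-ratio tests; a single variance
component tested on its boundary uses the ½χ²₀ + ½χ²₁ mixture null.

The restricted log-likelihood (up to its usual constant) is

    l_R(σ²) = -½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy ],
    P = V⁻¹ - V⁻¹X (XᵀV⁻¹X)⁻¹ XᵀV⁻¹.

The E main effect should always sit in X whenever A_ge is fitted —
otherwise a mean difference between exposure groups masquerades as
interaction variance; the drivers here add it automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

__all__ = [
    "reml_loglik",
    "VarianceComponentsREML",
    "fit_univariate",
    "lrt_component",
    "transform_phenotype",
    "VarianceComponentFit",
]


class RemlError(RuntimeError):
    pass


def _validate_model(y: np.ndarray, X: np.ndarray, mats: list[np.ndarray]):
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        raise ValueError("design matrix rows must match phenotype length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    for A in mats:
        if A.shape != (n, n):
            raise ValueError("relationship matrices must be n x n and conform to y")
    return y, X, mats


def _loglik_terms(y, X, V):
    """Restricted log-likelihood plus the P matrix and Py, via Cholesky."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        w = np.linalg.eigvalsh(V)
        raise RemlError(
            f"V is not positive definite (smallest eigenvalue {w[0]:.3e})"
        ) from err
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv = linalg.cho_solve((c, low), np.eye(V.shape[0]), check_finite=False)
    W = Vinv @ X
    XtVX = X.T @ W
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise RemlError("XᵀV⁻¹X is singular")
    P = Vinv - W @ np.linalg.solve(XtVX, W.T)
    Py = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    return ll, P, Py


def reml_loglik(
    y: np.ndarray,
    covmats: list[np.ndarray] | np.ndarray,
    sigmas: np.ndarray,
    X: np.ndarray | None = None,
    include_residual: bool = True,
) -> float:
    """Evaluate the restricted log-likelihood at given variance components.

    Parameters
    ----------
    y:
        Phenotype vector, length n.
    covmats:
        Relationship matrices; if ``include_residual`` the identity is
        appended automatically and ``sigmas`` must supply its variance last.
    sigmas:
        One variance per covariance matrix (residual last).
    X:
        Fixed-effect design; defaults to an intercept column.
    """
    mats = [np.asarray(A, dtype=float) for A in covmats]
    if include_residual:
        mats = mats + [np.eye(len(np.ravel(y)))]
    sigmas = np.asarray(sigmas, dtype=float).ravel()
    if sigmas.size != len(mats):
        raise ValueError("one variance required per covariance matrix")
    if X is None:
        X = np.ones((len(np.ravel(y)), 1))
    y, X, mats = _validate_model(y, X, mats)
    V = sum(s * A for s, A in zip(sigmas, mats))
    ll, _, _ = _loglik_terms(y, X, V)
    return ll


@dataclass
class VarianceComponentFit:
    """Result of a univariate variance-component fit."""

    estimates: np.ndarray
    se: np.ndarray
    names: list[str]
    proportions: np.ndarray
    proportions_se: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int
    at_bound: np.ndarray
    trace: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.names,
                "estimate": self.estimates,
                "se": self.se,
                "proportion": self.proportions,
                "proportion_se": self.proportions_se,
                "at_bound": self.at_bound,
            }
        )


class VarianceComponentsREML(BaseEstimator):
    """Average-information REML estimator for variance components.

    scikit-learn style: hyperparameters in ``__init__``, data in ``fit``,
    fitted results in trailing-underscore attributes.  The kernel list
    (relationship matrices) is data, passed to ``fit`` alongside y.

    Parameters
    ----------
    max_iter:
        Iteration cap; exceeding it raises with the iteration trace.
    tol:
        Convergence threshold on the relative restricted log-likelihood
        change between iterations.
    constrain:
        Keep all components non-negative (active-set clamping).  Set False
        for the unconstrained fit sometimes preferred when constructing
        LRTs.
    bound_tol:
        Estimates within this fraction of phenotypic variance of zero are
        flagged ``at_bound``.
    """

    def __init__(
        self,
        max_iter: int = 200,
        tol: float = 1e-8,
        constrain: bool = True,
        bound_tol: float = 1e-5,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.constrain = constrain
        self.bound_tol = bound_tol

    # -- estimator surface -------------------------------------------------
    def fit(self, K, y, X=None, names=None):
        """Fit variance components.

        Parameters
        ----------
        K:
            List of n×n relationship matrices (a residual identity is
            appended automatically; do not include it).
        y:
            Phenotype vector.
        X:
            Fixed-effect design; defaults to an intercept.
        names:
            Labels for the components; residual is labelled ``residual``.
        """
        mats = [np.asarray(A, dtype=float) for A in K]
        if not mats:
            raise ValueError("at least one relationship matrix is required")
        n = len(np.ravel(y))
        mats = mats + [np.eye(n)]
        if X is None:
            X = np.ones((n, 1))
        y, X, mats = _validate_model(np.ravel(y), X, mats)
        if names is None:
            names = [f"K{i + 1}" for i in range(len(mats) - 1)]
        names = list(names) + ["residual"]
        self._check_identifiable(mats)

        fit = _ai_reml(
            y,
            X,
            mats,
            names,
            max_iter=self.max_iter,
            tol=self.tol,
            constrain=self.constrain,
            bound_tol=self.bound_tol,
        )
        self.fit_ = fit
        self.estimates_ = fit.estimates
        self.se_ = fit.se
        self.proportions_ = fit.proportions
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        return self

    @staticmethod
    def _check_identifiable(mats):
        # two proportional covariance matrices cannot be separated
        flat = [A / np.linalg.norm(A) for A in mats]
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                if np.abs(np.vdot(flat[i], flat[j])) > 1 - 1e-12:
                    raise ValueError(
                        "relationship matrices are proportional (component "
                        f"{i + 1} vs {j + 1}): variance components are not identifiable"
                    )


def _ai_reml(y, X, mats, names, max_iter, tol, constrain, bound_tol):
    n = y.size
    k = len(mats)
    vary = float(np.var(y, ddof=1))
    if vary == 0:
        raise ValueError("phenotype is constant")
    floor = 1e-8 * vary
    theta = np.full(k, vary / k)
    trace = []

    ll, P, Py = _loglik_terms(y, X, sum(t * A for t, A in zip(theta, mats)))
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        # score and average-information matrix at the current point
        APy = [A @ Py for A in mats]
        yPAPy = np.array([float(Py @ v) for v in APy])
        trPA = np.array([float(np.sum(P * A)) for A in mats])  # A symmetric
        score = 0.5 * (yPAPy - trPA)
        PAPy = [P @ v for v in APy]
        AI = 0.5 * np.array([[float(APy[i] @ PAPy[j]) for j in range(k)] for i in range(k)])

        if constrain:
            free = ~((theta <= floor) & (score < 0))
        else:
            free = np.ones(k, dtype=bool)
        step = np.zeros(k)
        ai_free = AI[np.ix_(free, free)]
        try:
            step[free] = np.linalg.solve(ai_free, score[free])
        except np.linalg.LinAlgError:
            step[free] = theta[free] ** 2 * (yPAPy[free] - trPA[free]) / n  # EM
        # use a damped EM step on the first iteration for stability
        if it == 1:
            step = theta**2 * (yPAPy - trPA) / n

        accepted = False
        for _ in range(30):
            prop = theta + step
            if constrain:
                prop = np.maximum(prop, floor)
            try:
                ll_new, P_new, Py_new = _loglik_terms(
                    y, X, sum(t * A for t, A in zip(prop, mats))
                )
            except RemlError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM step as a guaranteed-ascent fallback
            prop = theta + theta**2 * (yPAPy - trPA) / n
            prop = np.maximum(prop, floor)
            ll_new, P_new, Py_new = _loglik_terms(
                y, X, sum(t * A for t, A in zip(prop, mats))
            )
        rel_change = abs(ll_new - ll) / max(1.0, abs(ll_new))
        trace.append((it, ll_new, prop.copy()))
        theta, ll, P, Py = prop, ll_new, P_new, Py_new
        if rel_change < tol:
            converged = True
            break

    if not converged:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations; trace: "
            + "; ".join(f"it{t[0]} ll={t[1]:.6f}" for t in trace[-5:])
        )

    # AI matrix at the optimum -> sampling covariance of the estimates
    APy = [A @ Py for A in mats]
    PAPy = [P @ v for v in APy]
    AI = 0.5 * np.array([[float(APy[i] @ PAPy[j]) for j in range(k)] for i in range(k)])
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)

    total = theta.sum()
    props = theta / total
    # delta method for Var(theta_i / total)
    grad = -np.outer(theta, np.ones(k)) / total**2 + np.diag(np.full(k, 1.0 / total))
    props_se = np.sqrt(np.maximum(np.einsum("ik,kl,il->i", grad, cov, grad), 0.0))

    at_bound = (theta <= max(bound_tol * vary, 2 * floor)) & constrain
    if at_bound.any():
        labs = [names[i] for i in np.where(at_bound)[0]]
        warnings.warn(f"variance component(s) at the zero bound: {labs}", stacklevel=3)
    return VarianceComponentFit(
        estimates=theta,
        se=se,
        names=names,
        proportions=props,
        proportions_se=props_se,
        loglik=ll,
        n=n,
        converged=converged,
        n_iter=n_iter,
        at_bound=at_bound,
        trace=trace,
    )


def fit_univariate(
    y: np.ndarray,
    grms: list,
    X: np.ndarray | None = None,
    names: list[str] | None = None,
    **kwargs,
) -> VarianceComponentFit:
    """Functional wrapper around :class:`VarianceComponentsREML`.

    ``grms`` may be ``Grm`` objects or plain arrays.
    """
    mats = [g.values if hasattr(g, "values") and not isinstance(g, np.ndarray) else np.asarray(g) for g in grms]
    y = np.ravel(np.asarray(y, dtype=float))
    if y.size < len(mats) + 1 + (1 if X is None else np.atleast_2d(X).shape[1]) + 10:
        raise ValueError("too few observations for the number of parameters")
    est = VarianceComponentsREML(**kwargs)
    est.fit(mats, y, X=X, names=names)
    return est.fit_


@dataclass
class LrtResult:
    statistic: float
    df: int
    p_value: float
    boundary: bool


def lrt_component(
    full_loglik: float,
    reduced_loglik: float,
    df: int = 1,
    boundary: bool = True,
    tol: float = 1e-3,
) -> LrtResult:
    """Likelihood-ratio test between nested REML fits.

    ``boundary=True`` applies the ½χ²₀ + ½χ²₁ mixture reference appropriate
    when a single variance component is tested on its zero boundary
    (requires df == 1); otherwise the plain χ²_df reference is used.

    Accepts either fit objects with a ``loglik`` attribute or floats.
    """
    lf = getattr(full_loglik, "loglik", full_loglik)
    lr = getattr(reduced_loglik, "loglik", reduced_loglik)
    if lr > lf + tol:
        raise RemlError(
            f"reduced-model log-likelihood ({lr:.6f}) exceeds the full model's "
            f"({lf:.6f}): one of the fits has not converged"
        )
    stat = max(0.0, 2.0 * (lf - lr))
    if boundary:
        if df != 1:
            raise ValueError("the boundary mixture reference applies to df=1 tests")
        p = 1.0 if stat <= 0 else 0.5 * stats.chi2.sf(stat, 1)
    else:
        p = 1.0 if stat <= 0 else float(stats.chi2.sf(stat, df))
    return LrtResult(statistic=stat, df=df, p_value=float(p), boundary=boundary)


def transform_phenotype(y: np.ndarray, method: str = "none") -> np.ndarray:
    """Deterministic phenotype transforms for scale-effect checks.

    ``rank-inverse-normal`` maps ranks (average ties, Blom offset 3/8) to
    normal quantiles, so any monotone transform of y yields the same
    output; ``log`` requires positive values; ``none`` is the identity.
    An interaction variance that shrinks after transformation is a scale
    effect rather than genuine effect-size heterogeneity.
    """
    y = np.asarray(y, dtype=float).ravel()
    if method == "none":
        return y.copy()
    if method == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive phenotypes")
        return np.log(y)
    if method in ("rank-inverse-normal", "rint"):
        r = stats.rankdata(y, method="average")
        return stats.norm.ppf((r - 3.0 / 8.0) / (y.size + 0.25))
    raise ValueError(f"unknown transform {method!r}")
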