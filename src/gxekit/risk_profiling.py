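"""Nested-model G×E tests in the risk-profiling framework.

For a binary outcome the full model is logistic:

    logit P(Y=1) = b0 + covariates + b_E E + Σ_p b_G,p G_p + Σ_p b_GE,p (G_p × E)

with one G and one G×E column per score partition.  Fitting the nested
sequence {covariates} ⊂ {+E} ⊂ {+G} ⊂ {+G×E} and comparing consecutive
maximised log-likelihoods yields likelihood-ratio χ² tests for the
environmental, genetic and interaction terms, with degrees of freedom equal
to the number of columns added.  Significant G and E main effects already
imply interaction on the observed disease scale; the explicit G×E term
addresses interaction on the underlying liability.  Quantitative outcomes
use the analogous linear nesting with F-tests.

Maximum-likelihood logistic fits are delegated to statsmodels; perfect
separation falls back to Firth's penalised likelihood (Jeffreys prior),
implemented here, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import RiskScoreSet, SampleVector

__all__ = [
    "NestedModelGxE",
    "fit_nested_models",
    "decile_odds_ratios",
    "firth_logistic",
]


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Firth-penalised logistic regression (Jeffreys-prior penalty).

    Newton iterations on the modified score U*(b) = Xᵀ(y - p + h(½ - p))
    with h the hat diagonal; finite estimates exist even under complete
    separation.  Returns (coef, penalised log-likelihood, converged).
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_ll(b):
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        I = (X * W[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(I)
        return ll + 0.5 * logdet

    ll_old = penalized_ll(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        XW = X * W[:, None]
        I = XW.T @ X
        Iinv = np.linalg.pinv(I)
        h = np.einsum("ij,jk,ik->i", XW, Iinv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        step = Iinv @ U
        for _ in range(25):
            ll_new = penalized_ll(beta + step)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        if abs(ll_new - ll_old) < tol * max(1.0, abs(ll_new)):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    return beta, ll_old, converged


@dataclass
class ProfileModelFit:
    name: str
    params: pd.Series
    bse: pd.Series
    loglik: float
    n: int
    converged: bool
    firth: bool = False


def _fit_logistic(X: pd.DataFrame, y: np.ndarray, name: str) -> ProfileModelFit:
    Xa = X.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # promote separation warnings
        try:
            res = sm.Logit(y, Xa).fit(method="newton", disp=0, maxiter=100)
            if np.isfinite(res.llf) and res.mle_retvals.get("converged", False):
                return ProfileModelFit(
                    name=name,
                    params=pd.Series(res.params, index=X.columns),
                    bse=pd.Series(res.bse, index=X.columns),
                    loglik=float(res.llf),
                    n=len(y),
                    converged=True,
                )
        except Exception:
            pass
    warnings.warn(
        f"model {name!r}: separation or non-convergence in the ML fit; "
        "falling back to Firth-penalised likelihood",
        stacklevel=3,
    )
    beta, pll, conv = firth_logistic(Xa, y)
    eta = Xa @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())  # unpenalised, for LRTs
    p = 1.0 / (1.0 + np.exp(-eta))
    I = (Xa * (p * (1 - p))[:, None]).T @ Xa
    bse = np.sqrt(np.diag(np.linalg.pinv(I)))
    return ProfileModelFit(
        name=name,
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        loglik=ll,
        n=len(y),
        converged=conv,
        firth=True,
    )


def _fit_linear(X: pd.DataFrame, y: np.ndarray, name: str) -> ProfileModelFit:
    res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    return ProfileModelFit(
        name=name,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        loglik=float(res.llf),
        n=len(y),
        converged=True,
    )


class NestedModelGxE(BaseEstimator):
    """Nested G/E/G×E model sequence with likelihood-ratio tests.

    Parameters
    ----------
    standardize_scores:
        Z-score the G columns before building main and interaction terms
        (the LRTs are invariant to this affine choice; it only aids
        coefficient readability).
    family:
        ``auto`` uses logistic models when the phenotype is binary and the
        linear nesting with F-tests otherwise.
    min_obs_per_param:
        Complete-case n below ``min_obs_per_param × parameters`` triggers a
        warning.

    Fitted attributes: ``fits_`` (per-model ProfileModelFit), ``anova_``
    (per-term LRT/F table with Nagelkerke or R² increments), ``n_used_``.
    """

    def __init__(
        self,
        standardize_scores: bool = True,
        family: str = "auto",
        min_obs_per_param: int = 10,
        bonferroni: bool = True,
    ):
        self.standardize_scores = standardize_scores
        self.family = family
        self.min_obs_per_param = min_obs_per_param
        self.bonferroni = bonferroni

    def fit(self, scores, y, env, covariates=None):
        """Fit the nested sequence.

        Parameters
        ----------
        scores:
            RiskScoreSet or array (n × p) of score columns.
        y:
            Binary (0/1) or quantitative phenotype; SampleVector or array.
        env:
            Environmental moderator; SampleVector or array.
        covariates:
            Optional n × c array (an intercept is always included).
        """
        if isinstance(scores, RiskScoreSet):
            G = scores.scores
            part_names = list(scores.partitions)
            samples = scores.samples
        else:
            G = np.atleast_2d(np.asarray(scores, dtype=float))
            if G.shape[0] == 1:
                G = G.T
            part_names = [f"G{i + 1}" for i in range(G.shape[1])]
            samples = None
        yv = y.align_to(samples) if isinstance(y, SampleVector) and samples is not None else (
            y.values if isinstance(y, SampleVector) else np.asarray(y, dtype=float)
        )
        ev = env.align_to(samples) if isinstance(env, SampleVector) and samples is not None else (
            env.values if isinstance(env, SampleVector) else np.asarray(env, dtype=float)
        )
        C = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
        if C is not None and C.shape[0] == 1:
            C = C.T

        mask = np.isfinite(yv) & np.isfinite(ev) & np.isfinite(G).all(axis=1)
        if C is not None:
            mask &= np.isfinite(C).all(axis=1)
        yv, ev, G = yv[mask], ev[mask], G[mask]
        C = None if C is None else C[mask]
        n = yv.size

        binary = np.isin(np.unique(yv), (0.0, 1.0)).all()
        if self.family == "auto":
            family = "logistic" if binary else "linear"
        else:
            family = self.family
        if family == "logistic" and np.unique(yv).size < 2:
            raise ValueError("phenotype must take two distinct values")
        if np.unique(ev).size < 2:
            raise ValueError("environment is constant: the interaction model is undefined")
        const_g = [part_names[j] for j in range(G.shape[1]) if np.unique(G[:, j]).size < 2]
        if const_g:
            raise ValueError(
                f"score column(s) {const_g} are constant: G and G×E terms are inestimable"
            )

        if self.standardize_scores:
            G = (G - G.mean(axis=0)) / G.std(axis=0)

        X = pd.DataFrame({"intercept": np.ones(n)})
        if C is not None:
            for j in range(C.shape[1]):
                X[f"covar{j + 1}"] = C[:, j]
        designs = [("covariates", X.copy())]
        X_e = X.copy()
        X_e["E"] = ev
        designs.append(("+E", X_e))
        X_g = X_e.copy()
        for j, nm in enumerate(part_names):
            X_g[f"G[{nm}]"] = G[:, j]
        designs.append(("+G", X_g))
        X_ge = X_g.copy()
        for j, nm in enumerate(part_names):
            X_ge[f"GxE[{nm}]"] = G[:, j] * ev
        designs.append(("+GxE", X_ge))

        n_params = designs[-1][1].shape[1]
        if n < self.min_obs_per_param * n_params:
            warnings.warn(
                f"complete-case n={n} is below {self.min_obs_per_param}x the "
                f"{n_params} parameters of the full model",
                stacklevel=2,
            )

        fitter = _fit_logistic if family == "logistic" else _fit_linear
        fits = [fitter(Xd, yv, nm) for nm, Xd in designs]

        rows = []
        ll0 = fits[0].loglik if family == "logistic" else None
        if family == "logistic":
            # Nagelkerke R² relative to the covariates-only baseline
            denom = 1.0 - np.exp(2.0 * ll0 / n)
        for prev, cur in zip(fits[:-1], fits[1:]):
            df = len(cur.params) - len(prev.params)
            stat = max(0.0, 2.0 * (cur.loglik - prev.loglik))
            if family == "logistic":
                p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
                r2_prev = (1.0 - np.exp(-2.0 * (prev.loglik - ll0) / n)) / denom
                r2_cur = (1.0 - np.exp(-2.0 * (cur.loglik - ll0) / n)) / denom
                incr = r2_cur - r2_prev
            else:
                # F-test between nested OLS fits
                rss_prev = _ols_rss(designs, prev.name, yv)
                rss_cur = _ols_rss(designs, cur.name, yv)
                df2 = n - len(cur.params)
                f = ((rss_prev - rss_cur) / df) / (rss_cur / df2)
                stat, p = f, float(stats.f.sf(f, df, df2))
                incr = (rss_prev - rss_cur) / _ols_rss(designs, "null_total", yv)
            rows.append(
                {
                    "term": cur.name.lstrip("+"),
                    "statistic": stat,
                    "df": df,
                    "p_value": p,
                    "r2_increment": incr,
                }
            )
        anova = pd.DataFrame(rows)
        if self.bonferroni:
            n_ge = len(part_names)
            anova["p_bonferroni"] = np.minimum(1.0, anova["p_value"] * np.where(
                anova["term"].eq("GxE"), n_ge, 1.0
            ))
        self.fits_ = {f.name: f for f in fits}
        self.anova_ = anova
        self.n_used_ = n
        self.family_ = family
        self.partitions_ = part_names
        return self

    @property
    def interaction_pvalue_(self) -> float:
        return float(self.anova_.loc[self.anova_["term"] == "GxE", "p_value"].iloc[0])


def _ols_rss(designs, name, y):
    if name == "null_total":
        return float(((y - y.mean()) ** 2).sum())
    Xd = dict(designs)[name].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    return float(resid @ resid)


def fit_nested_models(y, scores, env, covariates=None, **kwargs):
    """Functional wrapper: returns (per-model fits dict, LRT table)."""
    est = NestedModelGxE(**kwargs)
    est.fit(scores, y, env, covariates=covariates)
    return est.fits_, est.anova_


# ---------------------------------------------------------------------------
# decile stratification
# ---------------------------------------------------------------------------


def decile_odds_ratios(y, score, n_groups: int = 10) -> pd.DataFrame:
    """Odds of disease by score decile, relative to the bottom decile.

    Individuals are ranked on the score (ties broken by position, so the
    split is deterministic) and divided into ``n_groups`` near-equal
    groups.  OR_k = (cases_k/controls_k)/(cases_1/controls_1) with Woolf
    (log-scale normal) 95% confidence intervals.  Zero cells flag the OR
    as infinite or zero rather than erroring.
    """
    y = y.values if isinstance(y, SampleVector) else np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float).ravel()
    mask = np.isfinite(y) & np.isfinite(score)
    y, score = y[mask], score[mask]
    n = y.size
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} observations")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("decile odds require a binary 0/1 phenotype")
    order = np.argsort(score, kind="mergesort")
    groups = np.array_split(order, n_groups)
    rows = []
    base_cases = base_controls = None
    for k, idx in enumerate(groups, start=1):
        cases = float(y[idx].sum())
        controls = float(len(idx) - cases)
        odds = cases / controls if controls > 0 else np.inf
        if k == 1:
            base_cases, base_controls = cases, controls
        flag = ""
        if 0 in (cases, controls, base_cases, base_controls):
            flag = "zero_cell"
        if base_cases == 0:
            oratio = np.inf if cases > 0 else np.nan
        elif cases == 0:
            oratio = 0.0
        elif controls == 0 or base_controls == 0:
            oratio = np.inf if controls == 0 else (cases / controls) / (base_cases / base_controls)
        else:
            oratio = (cases / controls) / (base_cases / base_controls)
        if flag or k == 1:
            lo = hi = np.nan
        else:
            se = np.sqrt(1 / cases + 1 / controls + 1 / base_cases + 1 / base_controls)
            lo, hi = np.exp(np.log(oratio) + np.array([-1, 1]) * 1.96 * se)
        rows.append(
            {
                "decile": k,
                "n": len(idx),
                "cases": int(cases),
                "controls": int(controls),
                "odds": odds,
                "odds_ratio": 1.0 if k == 1 else oratio,
                "ci_low": lo,
                "ci_high": hi,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
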