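"""Phylogenetic generalized least squares under Pagel's lambda, with
all-subsets AIC model selection.

The regression model is y = X beta + e with e ~ N(0, sigma2 * C_lambda),
where C is the Brownian covariance of the tree and C_lambda its
lambda-transform.  For each candidate lambda the GLS estimates are closed
form, so lambda is profiled by one-dimensional bounded optimization of the
ML log-likelihood.  On an ultrametric tree lambda = 0 makes C_lambda
proportional to the identity, and the fit collapses to ordinary least
squares — which is why group means of the response are recovered exactly
when no phylogenetic signal is found.

Standard errors use the unbiased residual variance (denominator n - p) with
two-sided t tests on n - p degrees of freedom; the log-likelihood and AIC use
the ML variance (denominator n), with k = p + 2 parameters (coefficients
plus sigma2 and lambda).

Binary predictors are coded dioecious = 1, evergreen = 1, fleshy = 1 (the
second level in alphabetical order, as an R factor would be coded), and the
95th-percentile stem diameter enters untransformed in cm.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DesignMatrixError, DomainError, NumericError
from .phylogeny import PhyloCovariance, lambda_transform, phylo_covariance

PREDICTORS = ("sex_expression", "leaf_habit", "fruit_type", "dbh95_cm")

#: level mapped to 1 for each binary predictor
BINARY_CODING = {
    "sex_expression": "dioecious",
    "leaf_habit": "evergreen",
    "fruit_type": "fleshy",
}

LAMBDA_XATOL = 1e-8


@dataclass(frozen=True)
class ModelFit:
    """One fitted regression: estimates, inference, likelihood and AIC."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    lambda_hat: float
    loglik: float
    aic: float
    n: int
    k_params: int
    predictors: tuple[str, ...] = field(default=())
    error: str = ""

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "t_value": self.t_values,
                "p_value": self.p_values,
            }
        )


def design_matrix(
    traits: pd.DataFrame, predictors=PREDICTORS, response: str = "s50"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (y, X, term names) with an intercept and the coded predictors."""
    y = traits[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        missing = traits.loc[np.isnan(y), "species"].tolist()
        raise DomainError(f"response {response!r} missing for: {missing}")
    cols = [np.ones(len(traits))]
    names = ["(Intercept)"]
    for pred in predictors:
        if pred in BINARY_CODING:
            cols.append(
                (traits[pred] == BINARY_CODING[pred]).to_numpy(dtype=float)
            )
        else:
            cols.append(traits[pred].to_numpy(dtype=float))
        names.append(pred)
    return y, np.column_stack(cols), names


def _gls_core(y: np.ndarray, X: np.ndarray, M: np.ndarray):
    """GLS estimates and ML log-likelihood for a fixed covariance M."""
    n, p = X.shape
    try:
        cho = np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise NumericError("covariance not positive definite") from exc
    # whiten: solve L z = v
    Xw = np.linalg.solve(cho, X)
    yw = np.linalg.solve(cho, y)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < p:
        raise DesignMatrixError(
            "design matrix is rank deficient (collinear columns)"
        )
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    sigma2_ml = rss / n
    if sigma2_ml <= 0:
        raise NumericError("zero residual variance (saturated design)")
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    return beta, XtX_inv, rss, float(loglik)


def gls_fit(
    y,
    X,
    C,
    term_names: list[str] | None = None,
    lambda_hat: float = 1.0,
) -> ModelFit:
    """Generalized least squares with known covariance.

    beta = (X' C^-1 X)^-1 X' C^-1 y; standard errors from the unbiased
    residual variance rss/(n - p); the log-likelihood from the ML variance
    rss/n.  ``lambda_hat`` only annotates the result (use
    :func:`pgls_lambda` to estimate it).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]
    if len(y) != n or M.shape != (n, n):
        raise DomainError("y, X and C dimensions do not agree")

    beta, XtX_inv, rss, loglik = _gls_core(y, X, M)
    sigma2_unbiased = rss / (n - p) if n > p else np.nan
    se = np.sqrt(sigma2_unbiased * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df=max(n - p, 1))
    k = p + 2
    return ModelFit(
        terms=tuple(term_names),
        coefficients=dict(zip(term_names, beta.tolist())),
        std_errors=dict(zip(term_names, se.tolist())),
        t_values=dict(zip(term_names, t.tolist())),
        p_values=dict(zip(term_names, pvals.tolist())),
        lambda_hat=float(lambda_hat),
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n=n,
        k_params=k,
    )


def _coerce_covariance(tree_or_cov, taxa=None) -> PhyloCovariance:
    if isinstance(tree_or_cov, PhyloCovariance):
        cov = tree_or_cov
    elif isinstance(tree_or_cov, dendropy.Tree):
        cov = phylo_covariance(tree_or_cov)
    else:
        return PhyloCovariance(
            matrix=np.asarray(tree_or_cov, dtype=float),
            taxa=tuple(taxa) if taxa is not None else (),
        )
    if taxa is not None:
        cov = cov.reorder(list(taxa))
    return cov


def pgls_lambda(
    y,
    X,
    tree_or_cov,
    term_names: list[str] | None = None,
    taxa=None,
) -> ModelFit:
    """PGLS with lambda estimated by profiled maximum likelihood.

    For each lambda in [0, 1] the GLS coefficients and variance are closed
    form; the profile log-likelihood is maximized by bounded scalar search
    (with the endpoints checked), and the reported fit is the GLS fit at the
    optimum.  ``taxa`` (row order of y/X) aligns a tree-derived covariance.
    """
    cov = _coerce_covariance(tree_or_cov, taxa)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def ll_at(lam: float) -> float:
        return _gls_core(y, X, lambda_transform(cov, lam).matrix)[3]

    res = optimize.minimize_scalar(
        lambda lam: -ll_at(lam),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": LAMBDA_XATOL},
    )
    candidates = [(float(res.x), -res.fun), (0.0, ll_at(0.0)), (1.0, ll_at(1.0))]
    lam_hat, _ = max(candidates, key=lambda t: t[1])
    return gls_fit(
        y,
        X,
        lambda_transform(cov, lam_hat),
        term_names=term_names,
        lambda_hat=lam_hat,
    )


def all_subsets(
    traits: pd.DataFrame,
    tree_or_cov,
    response: str = "s50",
    predictors=PREDICTORS,
) -> list[ModelFit]:
    """Fit every predictor subset (intercept always included) and rank by AIC.

    All 2^k subsets of ``predictors`` are fitted by :func:`pgls_lambda`; the
    list is sorted by ascending AIC, ties broken by fewer parameters, then by
    the lexicographic tuple of predictor names.  A subset whose fit fails is
    recorded with ``aic = inf`` rather than aborting the scan.
    """
    cov = _coerce_covariance(tree_or_cov, taxa=list(traits["species"]))
    fits: list[ModelFit] = []
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            y, X, names = design_matrix(traits, subset, response=response)
            try:
                fit = pgls_lambda(y, X, cov, term_names=names)
                fit = dataclasses.replace(fit, predictors=subset)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                fit = ModelFit(
                    terms=tuple(names),
                    coefficients={},
                    std_errors={},
                    t_values={},
                    p_values={},
                    lambda_hat=np.nan,
                    loglik=-np.inf,
                    aic=np.inf,
                    n=len(traits),
                    k_params=len(names) + 2,
                    predictors=subset,
                    error=f"{type(exc).__name__}: {exc}",
                )
            fits.append(fit)
    fits.sort(key=lambda f: (f.aic, f.k_params, f.predictors))
    return fits
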