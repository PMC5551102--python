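"""Phylogenetic signal of a continuous trait: Blomberg's K and Pagel's lambda.

Both statistics ask whether related species resemble each other more than
expected by chance, but from different angles.

Blomberg's K compares the observed ratio of among-species variance (around
the GLS root-state estimate) to the Brownian-expected contrast variance,
scaled so that K = 1 is exactly the Brownian-motion expectation for the given
tree; K < 1 means less resemblance among relatives than Brownian motion
predicts.  Its significance comes from permuting trait values across tips and
asking how often the phylogenetically weighted mean squared error is as small
as observed.

Pagel's lambda is fitted by maximum likelihood under a multivariate normal
model whose covariance is the lambda-transformed tree covariance; lambda = 0
is phylogenetic independence, lambda = 1 Brownian motion.  Significance comes
from a likelihood-ratio test against lambda = 0 on one degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, NumericError
from .phylogeny import PhyloCovariance

LAMBDA_XATOL = 1e-8


@dataclass(frozen=True)
class SignalResult:
    """Outcome of one phylogenetic-signal test."""

    statistic_name: str          # "K" or "lambda"
    estimate: float
    p_value: float
    n_permutations: int | None = None      # K only
    loglik_at_estimate: float | None = None  # lambda only
    loglik_at_null: float | None = None      # lambda only


def _as_matrix(C) -> np.ndarray:
    return C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)


def phylo_mean(x, C) -> float:
    """GLS estimate of the root state: (1' C^-1 1)^-1 1' C^-1 x."""
    M = _as_matrix(C)
    x = np.asarray(x, dtype=float)
    if x.size != M.shape[0]:
        raise DomainError("trait vector length must match covariance dimension")
    try:
        w = np.linalg.solve(M, np.ones_like(x))
    except np.linalg.LinAlgError as exc:
        raise NumericError("singular phylogenetic covariance") from exc
    return float(w @ x / w.sum())


def _k_pieces(x: np.ndarray, M: np.ndarray):
    """(MSE0, MSE, expected ratio) for Blomberg's K."""
    n = x.size
    Minv_1 = np.linalg.solve(M, np.ones(n))
    ahat = Minv_1 @ x / Minv_1.sum()
    r = x - ahat
    mse0 = r @ r / (n - 1)
    mse = r @ np.linalg.solve(M, r) / (n - 1)
    expected = (np.trace(M) - n / Minv_1.sum()) / (n - 1)
    return mse0, mse, expected


def blomberg_k(x, C) -> float:
    """Blomberg's K: observed MSE0/MSE scaled by its Brownian expectation."""
    M = _as_matrix(C)
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DomainError("Blomberg's K needs at least 3 species")
    if np.ptp(x) == 0:
        raise DomainError("trait is constant across species; K is undefined")
    try:
        mse0, mse, expected = _k_pieces(x, M)
    except np.linalg.LinAlgError as exc:
        raise NumericError("singular phylogenetic covariance") from exc
    return float((mse0 / mse) / expected)


def blomberg_k_test(x, C, n_perm: int = 999, seed: int | None = None) -> SignalResult:
    """Permutation test for Blomberg's K.

    Trait values are shuffled across tips ``n_perm`` times; the p-value is the
    smoothed fraction of permutations whose phylogenetically weighted MSE is
    at most the observed one (lower MSE = more signal), the observed
    arrangement counting as one permutation.  Bit-for-bit reproducible for a
    given seed.
    """
    M = _as_matrix(C)
    x = np.asarray(x, dtype=float)
    k_obs = blomberg_k(x, C)  # also validates input

    n = x.size
    Minv = np.linalg.inv(M)
    Minv_1 = Minv @ np.ones(n)
    s = Minv_1.sum()

    def weighted_sse(xs: np.ndarray) -> np.ndarray:
        # rows of xs are permuted trait vectors; residual about the GLS mean
        ahat = xs @ Minv_1 / s
        return np.einsum("ij,jk,ik->i", xs, Minv, xs) - s * ahat**2

    mse_obs = weighted_sse(x[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    mse_perm = weighted_sse(x[perms])
    p = (1 + int(np.sum(mse_perm <= mse_obs))) / (1 + n_perm)
    return SignalResult(
        statistic_name="K", estimate=k_obs, p_value=float(p), n_permutations=n_perm
    )


def lambda_loglik(x, C, lam: float) -> float:
    """Profile log-likelihood of lambda (root state and rate profiled out).

    ln L = -1/2 [n ln(2 pi sigma2) + ln|C_lam| + n] with the GLS root state
    and the ML rate sigma2 = r' C_lam^-1 r / n plugged in.
    """
    M = _as_matrix(C)
    x = np.asarray(x, dtype=float)
    n = x.size
    Clam = lam * M
    np.fill_diagonal(Clam, np.diag(M))
    try:
        cho = np.linalg.cholesky(Clam)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"C_lambda not positive definite at lambda={lam}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho)))
    ones = np.ones(n)
    Ci_1 = np.linalg.solve(Clam, ones)
    ahat = Ci_1 @ x / (Ci_1 @ ones)
    r = x - ahat
    sigma2 = r @ np.linalg.solve(Clam, r) / n
    if sigma2 <= 0:
        raise NumericError("non-positive ML variance in lambda likelihood")
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda_ml(x, C) -> SignalResult:
    """Maximum-likelihood Pagel's lambda with a likelihood-ratio test.

    Lambda is maximized over [0, 1] by bounded scalar optimization; the
    p-value is from 2 * (lnL(lambda_hat) - lnL(0)) against chi-square with
    1 degree of freedom (null: no phylogenetic signal).  A warning is issued
    for non-ultrametric covariances (non-constant diagonal), where the
    transform is still defined but the usual interpretation weakens.
    """
    M = _as_matrix(C)
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DomainError("lambda estimation needs at least 3 species")
    d = np.diag(M)
    if np.ptp(d) > 1e-8 * d.max():
        warnings.warn(
            "covariance diagonal is not constant (tree not ultrametric); "
            "lambda estimates may be hard to interpret",
            stacklevel=2,
        )

    def neg_ll(lam: float) -> float:
        return -lambda_loglik(x, M, lam)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(0.0, 1.0), method="bounded", options={"xatol": LAMBDA_XATOL}
    )
    if not res.success:
        raise NumericError(f"lambda optimizer failed: {res.message}")
    # guard against the bounded optimizer missing a boundary maximum
    candidates = [(float(res.x), -res.fun), (0.0, -neg_ll(0.0)), (1.0, -neg_ll(1.0))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll_0 = candidates[1][1]
    lrt = max(0.0, 2.0 * (ll_hat - ll_0))
    p = float(stats.chi2.sf(lrt, df=1))
    return SignalResult(
        statistic_name="lambda",
        estimate=lam_hat,
        p_value=p,
        loglik_at_estimate=ll_hat,
        loglik_at_null=ll_0,
    )
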