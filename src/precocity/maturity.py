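"""Size standardization and the logistic threshold of flowering.

The probability that an individual bears flowers is modelled as a logistic
function of log relative size,

    P(flower | S) = exp(a + b ln S) / (1 + exp(a + b ln S)),

where S is the individual's stem diameter divided by the species' maximum
size, estimated as the 95th percentile of measured diameters.  Setting
P = 0.5 gives the population-level onset of flowering

    S_0.5 = exp(-a / b),

the relative size at which half of the individuals flower.  For an increasing
size-flowering relationship (b > 0), S_0.5 is well defined and lies in
(0, inf); values near 0 mean precocious flowering, values near 1 mean
flowering only at near-maximal size.

The maximum-likelihood fit uses iteratively reweighted least squares (IRLS,
i.e. Newton scoring for the Bernoulli GLM with logit link).  Complete
separation — all small plants sterile, all large plants flowering — sends the
coefficients to infinity; fits whose coefficients exceed a magnitude of 50 at
termination are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateResponseError,
    DomainError,
    InsufficientDataError,
    SpeciesLookupError,
)

IRLS_TOL = 1e-10
IRLS_MAX_ITER = 100
SEPARATION_COEF = 50.0


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit of flowering on log relative size."""

    a: float                 # intercept
    b: float                 # slope on ln(relative size)
    loglik: float
    n: int
    converged: bool
    separation_flag: bool

    @property
    def s50(self) -> float:
        return s50(self.a, self.b)


@dataclass(frozen=True)
class MaturityEstimate:
    """Per-species onset-of-flowering summary: threshold, fit, and size scale."""

    species: str
    s50: float
    fit: LogisticFit
    dbh95_cm: float
    n: int


def percentile95(diameters) -> float:
    """95th percentile by linear interpolation of order statistics.

    Uses the index h = (n - 1) * 0.95 + 1 on the sorted sample, interpolating
    between the two bracketing order statistics (the default convention of R
    and numpy).  Requires at least two positive values.
    """
    x = np.asarray(diameters, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(
            f"need at least 2 diameters for a percentile, got {x.size}"
        )
    if not (x > 0).all():
        raise DomainError("diameters must be positive")
    return float(np.percentile(x, 95.0))


def relative_sizes(diameters, dbh95: float) -> np.ndarray:
    """Divide each diameter by the species' 95th-percentile diameter.

    Values above 1 are expected for roughly the top 5% of a sample
    standardized by its own 95th percentile.
    """
    if dbh95 <= 0:
        raise DomainError(f"dbh95 must be positive, got {dbh95}")
    return np.asarray(diameters, dtype=float) / float(dbh95)


def logistic_probability(sizes, a: float, b: float) -> np.ndarray:
    """P(flower) = expit(a + b ln S) for relative sizes S."""
    eta = a + b * np.log(np.asarray(sizes, dtype=float))
    # numerically stable expit
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum[y*eta - log(1 + exp(eta))], stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_flowering_logistic(sizes, flowered) -> LogisticFit:
    """Fit the flowering logistic P = expit(a + b ln S) by IRLS.

    Parameters
    ----------
    sizes : array-like of positive floats
        Relative plant sizes S.
    flowered : array-like of bool
        Whether each individual bore flowers.

    Returns
    -------
    LogisticFit
        ``converged`` is True when the log-likelihood improved by less than
        1e-10 within 100 iterations; ``separation_flag`` is True when a
        coefficient magnitude exceeds 50 at termination, the signature of
        (quasi-)complete separation.
    """
    S = np.asarray(sizes, dtype=float)
    y = np.asarray(flowered, dtype=float)
    if S.shape != y.shape:
        raise DomainError("sizes and flowered must have equal length")
    if S.size < 2:
        raise InsufficientDataError(f"need at least 2 observations, got {S.size}")
    if not (S > 0).all():
        raise DomainError("relative sizes must be positive")
    if y.min() == y.max():
        state = "flowered" if y[0] else "non-flowered"
        raise DegenerateResponseError(
            f"all {int(S.size)} individuals are {state}; "
            "the logistic threshold is undefined"
        )

    X = np.column_stack([np.ones_like(S), np.log(S)])
    beta = np.zeros(2)
    eta = X @ beta
    ll = _bernoulli_loglik(y, eta)
    converged = False
    for _ in range(IRLS_MAX_ITER):
        p = logistic_probability(S, beta[0], beta[1])
        w = np.clip(p * (1.0 - p), 1e-12, None)
        # Newton step with halving if the likelihood would decrease
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll = _bernoulli_loglik(y, X @ new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or (new_ll < ll and halvings < 30):
            step *= 0.5
            new_beta = beta + step
            new_ll = _bernoulli_loglik(y, X @ new_beta)
            halvings += 1
        beta = new_beta
        if abs(new_ll - ll) < IRLS_TOL:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    separation = bool(np.max(np.abs(beta)) > SEPARATION_COEF)
    return LogisticFit(
        a=float(beta[0]),
        b=float(beta[1]),
        loglik=float(ll),
        n=int(S.size),
        converged=converged and not separation,
        separation_flag=separation,
    )


def s50(a: float, b: float) -> float:
    """Relative size at which the fitted flowering probability is 0.5.

    S_0.5 = exp(-a/b); requires an increasing size-flowering relationship
    (b > 0), otherwise the 50% threshold does not exist.
    """
    if b <= 0:
        raise DomainError(
            f"s50 undefined for non-positive slope b={b} "
            "(flowering probability not increasing in size)"
        )
    return float(np.exp(-a / b))


def species_maturity(
    observations: pd.DataFrame, species_id: str, min_n: int = 20
) -> MaturityEstimate:
    """Estimate a species' relative size at onset of flowering.

    Selects the species' rows from the observation table, standardizes the
    diameters by their own 95th percentile, fits the flowering logistic and
    transforms to S_0.5.  ``min_n`` is the sampling floor (default 20
    individuals); pass a smaller value to relax it.
    """
    rows = observations[observations["species"] == species_id]
    if len(rows) == 0:
        raise SpeciesLookupError(species_id)
    if len(rows) < min_n:
        raise InsufficientDataError(
            f"{species_id}: {len(rows)} observations < required {min_n}"
        )
    diam = rows["diameter_cm"].to_numpy(dtype=float)
    dbh95 = percentile95(diam)
    S = relative_sizes(diam, dbh95)
    fit = fit_flowering_logistic(S, rows["flowered"].to_numpy(dtype=bool))
    return MaturityEstimate(
        species=species_id,
        s50=s50(fit.a, fit.b),
        fit=fit,
        dbh95_cm=dbh95,
        n=len(rows),
    )


def fit_all_species(
    observations: pd.DataFrame, min_n: int = 20
) -> pd.DataFrame:
    """Fit every species in an observation table.

    Returns a DataFrame (species, s50, dbh95_cm, n_obs, a, b, converged,
    separation_flag), one row per species, in first-appearance order.
    Species that fail the sampling floor or have a degenerate response are
    skipped with their error recorded in an ``error`` column.
    """
    rows = []
    for sp in pd.unique(observations["species"]):
        try:
            est = species_maturity(observations, sp, min_n=min_n)
            rows.append(
                {
                    "species": sp,
                    "s50": est.s50,
                    "dbh95_cm": est.dbh95_cm,
                    "n_obs": est.n,
                    "a": est.fit.a,
                    "b": est.fit.b,
                    "converged": est.fit.converged,
                    "separation_flag": est.fit.separation_flag,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-species failures are data
            rows.append(
                {
                    "species": sp,
                    "s50": np.nan,
                    "dbh95_cm": np.nan,
                    "n_obs": int((observations["species"] == sp).sum()),
                    "a": np.nan,
                    "b": np.nan,
                    "converged": False,
                    "separation_flag": False,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(rows)
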