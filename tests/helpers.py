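"""Independent brute-force oracles used to cross-check the optimizers."""

import numpy as np

from precocity.phylogeny import PhyloCovariance
from precocity.signal import lambda_loglik


def logistic_grid_mle(sizes, flowered, a_range=(-30.0, 30.0), b_range=(-30.0, 60.0)):
    """Maximize the Bernoulli log-likelihood over (a, b) by zooming grid search.

    Deliberately independent of the IRLS code path: evaluates the likelihood
    surface on a 61x61 grid and shrinks the window around the argmax until the
    grid resolution is ~1e-6.
    """
    S = np.asarray(sizes, dtype=float)
    y = np.asarray(flowered, dtype=float)
    lnS = np.log(S)
    a_lo, a_hi = a_range
    b_lo, b_hi = b_range
    m = 61
    best = (0.0, 0.0)
    for _ in range(14):
        A = np.linspace(a_lo, a_hi, m)
        B = np.linspace(b_lo, b_hi, m)
        eta = A[:, None, None] + B[None, :, None] * lnS[None, None, :]
        ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (A[i], B[j])
        da = (a_hi - a_lo) / (m - 1)
        db = (b_hi - b_lo) / (m - 1)
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
        if da < 1e-6 and db < 1e-6:
            break
    return best


def lambda_grid_argmax(x, cov: PhyloCovariance, step: float = 1e-3) -> float:
    """Argmax of the lambda profile likelihood on a regular grid."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    lls = [lambda_loglik(x, cov, lam) for lam in grid]
    return float(grid[int(np.argmax(lls))])
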