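# Methods

## Threshold of flowering

Each species' onset of flowering is summarized by the relative size at which
half the individuals bear flowers. Relative size is stem diameter divided by
the species' 95th percentile of measured diameters (a robust stand-in for
maximum size; the percentile uses linear interpolation of order statistics
with index h = (n−1)·0.95 + 1, the R/numpy default, so published size maxima
are reproducible in principle). Because a sample is standardized by its own
95th percentile, about 5% of relative sizes exceed 1 by construction.

Flowering probability is modelled as logistic in log relative size,
P = expit(a + b ln S), fitted by iteratively reweighted least squares with
step halving; convergence is declared when the log-likelihood improves by
less than 1e−10 within 100 iterations. The threshold is S₀.₅ = exp(−a/b),
defined only for b > 0 (probability increasing in size). Fits with any
coefficient magnitude above 50 are flagged as (quasi-)separated; their
threshold is still reported — under separation it approaches the boundary
between flowering and non-flowering sizes, which is a reasonable estimate —
but `converged` is false. Species with all-flowered or all-sterile records
have no estimable threshold and raise a degenerate-response error (the
pipeline records and skips them). The default sampling floor is 20
individuals per species, relaxable by argument. No confidence intervals are
attached to S₀.₅, and no sex-specific thresholds are fitted.

## Tree construction and calibration

With no molecular data in scope, the species tree is assembled from
taxonomy: each species is grafted under its genus and family onto a bundled
backbone newick of the 18 studied families whose topology follows APG-III
relationships (magnoliids sister to eudicots within mesangiosperms; fabids
and malvids within rosids; Cornales, then Ericales, then lamiids/campanulids
within asterids). Genera within families and species within genera form
polytomies wherever taxonomy provides no resolution.

Branch lengths come from a clade-age table by the bladj rule: named nodes
found in the table are fixed, tips are fixed at age 0, and each undated
node — visited root-to-tip — is placed by even spacing between its already
dated parent and its most constraining fixed descendant (the oldest of the
even-spacing candidates over fixed descendants; this tie-break keeps ages
monotone down every path, and reduces to plain even spacing along chains).
Branch length is parent age minus child age, so the calibrated tree is
ultrametric exactly. The bundled `node_ages.csv` carries approximate
family/order ages (Ma) of the magnitudes used in standard angiosperm age
compilations (root at 179 Ma); these set relative node depths, which is the
only thing the downstream statistics see. Because the age table is
approximate, point values of the signal statistics are treated as
tree-dependent: the tests assert their qualitative behaviour (both
non-significant on the study data) and their exact agreement with an
independent implementation on a frozen fixture tree, not specific published
point values.

Polytomies are resolved uniformly at random (seeded, default 1) with
zero-length internal branches, which leaves the covariance matrix — hence
every downstream estimate except the permutation stream — unchanged.

## Signal statistics

Blomberg's K uses the GLS root-state estimate â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x and
compares MSE₀/MSE (numerator: variance about â; denominator:
phylogenetically weighted residual MSE) against its Brownian expectation
(tr C − n/1ᵀC⁻¹1)/(n−1), so K = 1 exactly on star trees and under Brownian
motion in expectation. Significance is by permutation of trait values across
tips (default 999), counting permutations whose weighted MSE is at most the
observed one, with the observed arrangement included (+1 smoothing) — the
permutation statistic is the MSE, which is order-equivalent to K itself.

Pagel's λ is estimated by maximizing the profile normal log-likelihood over
λ ∈ [0, 1] (bounded scalar search, tolerance 1e−8, endpoints checked;
values above 1 are not considered). The root state and rate σ² are profiled
analytically at each λ. The likelihood-ratio test is against λ = 0 (no
signal) on one χ² degree of freedom; with truth on that boundary the test is
conservative, which the suite verifies by simulation. ML, not REML, is used
throughout, matching the regression module.

## Regression and model selection

PGLS under the λ model profiles λ exactly as above, with the GLS coefficient
vector closed-form at each λ via Cholesky whitening. Standard errors use the
unbiased residual variance (denominator n − p) with two-sided t tests on
n − p degrees of freedom; the log-likelihood and AIC use the ML variance
(denominator n) and k = p + 2 parameters (coefficients, σ², λ). Binary
predictors are coded to 1 for the alphabetically second level — dioecious,
evergreen, fleshy — as an R factor would be, so the sex-only intercept is
the cosexual group mean; maximum size (the 95th-percentile diameter) enters
untransformed in cm. All 2⁴ subsets of the four predictors are fitted with λ
re-estimated per subset (on the study data every subset drives λ̂ to 0, so
the distinction from a shared λ is moot); ranking is by AIC, ties broken by
fewer parameters then predictor names. On an ultrametric tree λ = 0 makes
C_λ proportional to the identity and the fit collapses to OLS — which is why
the study's regression table is reproducible without the original
calibrated tree, while the absolute AIC values do retain a dependence on the
root age through ln|C_λ|.

A degenerate subset (rank-deficient design, saturated fit) is recorded with
infinite AIC rather than aborting the scan, so minimal studies (down to 3
species) still run end to end.

## Synthetic studies

The generator mirrors the study design rather than idealizing it. Defaults:
30 species on a unit-depth Yule tree (pure-birth, rate 1, with the clock run
on past the last birth so no tip branch is zero), thresholds drawn from the
λ-Brownian model with λ = 0.1, baseline 0.33 and variance 0.015 (between-
species SD ≈ 0.12, the scale of the study's threshold spread), a marked
"dioecious" subset of 11/30 species shifted by −0.166, logistic slopes
uniform on (3, 8) (the worked species fit has b ≈ 4.8), 60 individuals per
species (≈ 1789/30), and per-species maximum sizes log-uniform on 6–70 cm.
True thresholds are clipped to (0.02, 0.98); individual diameters are
log-uniform on (0.05, 1.2) × the species maximum. Everything is a pure
function of (config, seed).

Two consequences of that design matter when interpreting recovery tests.
First, a species whose true threshold falls at or below the sampled size
floor (relative size 0.05) flowers at essentially every sampled size, so no
threshold is estimable and the species drops out — a real phenomenon in
field data too (a species already mature at the smallest surveyed size).
Second, clipping and those drop-outs shrink the realized marked-vs-unmarked
difference below the nominal generating effect. End-to-end recovery is
therefore judged against the realized true group difference among the
species entering the regression (available from the truth record); measured
that way the regression coefficient is unbiased to well under 10% of the
effect. What the generator does not emulate: measurement error in diameters,
sex-ratio structure within species, phylogenetically clustered trait
assignment (available as a stress-test option is deliberately out of the
defaults since the study treats sex expression as fixed), and non-uniform
size distributions; passing recovery tests says nothing about those.

## Numerical choices and problem sizes

Logistic IRLS: tolerance 1e−10, 100 iterations, separation threshold 50.
λ searches: bounded Brent, xatol 1e−8, endpoints always evaluated.
Covariance solves use Cholesky factorizations; the λ transform preserves
positive semidefiniteness on ultrametric trees, which the suite checks on
random Yule trees. Permutation p-values are smoothed (+1) multiples of
1/(n_perm + 1) and bit-reproducible given a seed. The test suite sizes its
simulations for a single CPU: type-I-error calibration uses 500 replicates
of a 16-tip tree with 999 permutations; λ recovery uses 100 replicates at
128 tips; end-to-end effect recovery uses 100 replicates of 60 species × 300
individuals. These sizes were chosen to keep Monte-Carlo error comfortably
inside the asserted bands.

## Known limitations

Ages in the bundled table are approximate; analyses sensitive to absolute
node ages (e.g. comparing AIC values across differently calibrated trees)
should supply their own age table. The taxonomy tree cannot resolve
relationships below the genus level. λ is restricted to [0, 1], so traits
more dispersed than Brownian motion (λ > 1 under wider definitions) are
reported at the boundary. The K permutation test assumes exchangeability of
tips under the null; the λ LRT p-value is asymptotic and conservative at the
λ = 0 boundary.
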