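# Methods

## Estimator

The package fits a recursive composite SEM: latent variables are weighted
sums of their indicator blocks, and structural relations among the latent
scores are estimated by per-equation ordinary least squares. The weighting
scheme is principal-component based and *one-shot*:

1. Standardise every indicator column (sample sd, n − 1 denominator).
2. Per block, take the dominant eigenvector of the block covariance matrix
   (for standardised data, the correlation matrix), computed by a full
   symmetric eigendecomposition — blocks are small, so no truncated or
   iterative solver is warranted.
3. Normalise that eigenvector so its absolute components sum to one; this is
   the final outer weight vector. Single-indicator blocks get weight 1.
4. Latent scores t = Xw are re-standardised to mean 0 / variance 1.
5. Outer loadings are Pearson correlations between each indicator and its
   own latent's score; path coefficients are one OLS multiple regression per
   endogenous latent on its direct parents' scores.
6. Total effects accumulate path products over every directed route
   (equivalently Σₖ Aᵏ for the coefficient matrix A of a DAG).
7. Location parameters: per latent, the (slope, intercept) of the exact
   affine map from the standardised score to the 0–100-scale score used by
   IPMA. Both scores are affine in the same weighted indicator combination,
   so the map is exact, not a regression approximation; the intercept equals
   the mean 0–100 score.

There is no outer/inner iteration loop. Classic PLS weighting schemes
(path, centroid, factor) alternate approximations until weight changes fall
below ~1e-5; the PCA scheme replaces that loop with a single eigenvector
extraction, making the fit deterministic and immune to convergence failures.
The iterative schemes are deliberately not offered as alternatives.

**Sign convention.** Eigenvectors are sign-ambiguous. Weights are oriented
so the component of largest absolute value (first on ties) is positive — a
deterministic, dataset-independent rule. Other software may report a block
with globally flipped signs; comparisons should be made up to sign.

**Re-standardisation choice.** Raw scores Xw under abs-sum-one weights do
not have unit variance. Scores are re-standardised before loadings and OLS
so that loadings are correlations and path coefficients are standardised
coefficients; the abs-sum-one weights are retained for the IPMA stage. This
behaviour is pinned by tests.

**What the composite estimates.** Composite scores are proxies for the
latent variables, and the estimands differ from factor-model parameters in
a predictable way: for a block of I indicators with common factor loading λ,
the population composite loading is √(((I−1)λ² + 1)/I) (inflated, because an
indicator is correlated with its own error inside the composite), and a
structural path is attenuated by the product of the two blocks' score
reliabilities λ√I/√((I−1)λ² + 1). The test suite checks recovery against
these composite estimands where block sizes are small, and against the
generating values for the aggregate median-error criteria, where
single-indicator and large blocks keep the pooled error small.

**Degenerate inputs.** Zero-variance columns, all-zero blocks, and perfectly
collinear parent scores raise typed errors naming the offender; missing
values are rejected (complete cases required; imputation is out of scope).

## Evaluation statistics

AVE = Σλ² / (Σλ² + Σ(1 − λ²)), which algebraically equals mean(λ²) under
var(ε) = 1 − λ²; the full ratio is implemented and the identity is asserted
in tests. Composite reliability ρ_c = (Σλ)² / ((Σλ)² + Σ(1 − λ²)).
Indicators are valid when loading > 0.5 (strict). Discriminant validity uses
cross-loadings (own-latent correlation must strictly exceed all others;
ties fail) and Fornell–Larcker (√AVE on the diagonal must strictly exceed
each off-diagonal correlation magnitude). R² per endogenous latent is
computed by the decomposition Σ βₕ·corr(parentₕ, child), which equals
1 − SSE/SST on standardised scores (asserted against an independent OLS
refit); categories are weak < 0.33 ≤ moderate < 0.67 ≤ strong, boundary
values going to the higher category. GoF = √(mean AVE × mean R²);
`gof()` takes explicit value lists so the caller controls the averaging set.
Q² = 1 − Π(1 − Rⱼ²) over endogenous latents (the composite form, not
blindfolding by omission distance). Cronbach's alpha is not computed;
composite reliability is the reported internal-consistency measure for
composite models. Reports print 3 decimals, half-up; machine exports keep
full precision.

## Bootstrap

B resamples of n rows with replacement; the full estimator is refitted per
resample. Because a resample can flip a block's PCA orientation, each
replicate applies an individual sign-change correction: a block's weight
vector is flipped when its dot product with the original-sample weights is
negative, before scores, loadings and paths are computed — standard practice
for composite-model bootstrapping. SE is the sample SD of replicates
(B − 1); t = estimate/SE is referred to Student t with df = n − 1, two-
tailed. The n − 1 reference follows the convention for these tests; exact t
quantiles are always used (the familiar 1.96 cut-off is the large-df normal
shortcut). Resamples with a zero-variance column are discarded and counted;
more than 10% discarded aborts. Parameters whose replicates are identical up
to float jitter (e.g. a single-indicator loading, fixed at 1) are flagged
non-testable rather than given a meaningless t. Default B = 2000,
CLI-overridable; the resample stream is consumed in a fixed order, so a
given seed reproduces results bit-for-bit.

## IPMA

Indicators are rescaled to 0–100 by (x − min)/(max − min)·100 per
observation, with empirical per-column bounds by default and user-supplied
theoretical bounds optionally (violations raise). Rescaling is applied
per-observation; since the map is affine, means of rescaled values equal
rescaled means and performance is unaffected by that choice.
Unstandardised outer weights divide each standardised weight by the
indicator's 0–100-scale sd, then normalise each block to sum to one, so a
latent's 0–100 score is a weighted mean of its rescaled indicators.
A block whose unstandardised weights sum to ≤ 0 (possible with mixed-sign
weights) raises rather than producing an uninterpretable performance.

Importance is the *unstandardised* total effect on the target: the
structural equations are re-estimated by OLS (with intercept) on the
0–100-scale latent scores and path products are accumulated — not obtained
by ad-hoc sd-ratio rescaling of the standardised coefficients. Indicator
importance is the normalised weight times the latent importance, so block
indicator importances sum exactly to the latent importance. The target and
its indicators are excluded from the map.

Quadrants: crosshair at the mean importance/mean performance of plotted
items (fixed constants accepted); importance on x, performance on y (a flag
flips axes for the classic presentation where importance is vertical);
points on a crosshair line go to the higher side (≥ convention). Negative
importances — real when total effects are negative — are retained with
sign, never clipped; their quadrant reading must account for the
indicator's coding direction.

The full pipeline re-estimates the model after pruning indicators that are
invalid (loading ≤ 0.5) or whose loadings are not bootstrap-significant,
before IPMA; pruning is explicit, logged in the run manifest, never allowed
to empty a block, and can be disabled.

## Synthetic data generator

The generator draws data from the reflective composite model itself:
exogenous latents are standard normal; each endogenous latent is the
coefficient-weighted sum of its parents plus a disturbance scaled so the
population variance is exactly 1 — the implied latent covariance is
propagated in topological order, so correlated parents are handled exactly,
not approximately. Indicators are λ·latent + error with error variance
1 − λ², optionally affine-mapped to a (location, spread) scale. Errors are
Gaussian by default; a standardised shifted-lognormal option produces
clearly skewed errors for robustness checks. Single-indicator blocks use
loading 1 and no measurement error.

The default fixture (`district_profile_config`) emulates a district-level
malnutrition study: one exogenous socioeconomic construct (3 indicators),
three mediators — parenting and food security (1 indicator each), health &
environmental services (7) — and a 3-indicator malnutrition target; six
structural paths (0.464, 0.720, 0.513, −0.185, 0.178, −0.011); loadings 0.9
on multi-indicator blocks; n = 38 observational units by default, the
scale of a provincial district census. What it does **not** emulate:
spatial correlation between neighbouring districts, bounded/percentage
measurement scales with floor and ceiling effects, missingness, and
indicator-specific error correlations. Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own assumptions,
not robustness to those real-data features.

## Problem sizes used in the checks

Formula-reproduction checks run on printed block loadings (2–7 values).
The PCA-vs-eigensolver agreement check uses 100 random blocks of up to 8
indicators. Parameter recovery uses n = 5000 over 20 seeds. Bootstrap
calibration uses the minimal two-construct model at n = 200 with B = 500
over 200 Monte-Carlo repetitions for size and again for power — B chosen at
a quarter of the reporting default since calibration depends on B only
weakly. Coverage spot-checks use n = 500, B = 300, 40 repetitions.

## Known limitations

- Formative blocks are accepted structurally but evaluated only with a
  warning; formative outer-weight regression estimation is not implemented.
- No higher-order constructs, cyclic (non-recursive) models, moderation
  terms, consistent-PLS corrections, or multi-group extensions.
- Q² is the composite 1 − Π(1 − R²) form, not blindfolding.
- The location-parameter construction (affine link between standardised and
  0–100 scores) is one defensible definition among several used in the
  IPMA literature; it is exact under this package's weighting and is pinned
  by dual-construction tests.
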