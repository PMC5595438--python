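# Methods

## Trajectories

Per-gene trajectories are least-squares fits of expression on a natural
cubic spline of age plus additive covariates.  "Three degrees of
freedom" means a 3-column natural-spline basis: two interior knots at
the 33.3 %/66.7 % quantiles of *sample* ages (replicated ages weight the
quantiles) and boundary knots at the age range.  The basis replicates
the classical construction — a cubic B-spline basis projected onto the
null space of the zero-second-derivative constraints at the boundaries —
and is cross-checked in the test suite against R's `splines::ns` fitted
values to 1e-8.  Interpolation evaluates the fit on a regular grid
(default 0.1 y for humans, 1 d for mice) with categorical covariates at
their reference level and numeric covariates at their training mean;
there is no extrapolation beyond the boundary knots.  A lowess smoother
(default span 0.75, configurable) is available behind the same
trajectory interface.  Sex-stratified analyses refit each sex's samples
without a sex covariate.

## Turning points

The derivative is the first difference of adjacent grid values — the
central-difference estimate at the interval midpoints — so a sign change
between adjacent midpoints brackets a single grid age, which is reported
as the turning age.  Exact-zero stretches (possible only on idealized
data) are dated at their first age; a zero stretch after which the same
sign resumes is a saddle and is skipped.  Only the first turning point
per trajectory is kept.  ΔE is the trajectory value at the turning age
minus the value at the trajectory start; its sign defines the upward /
downward direction.  Turning ages are kept at grid resolution in the
table (`age`) with a whole-year/day rounding alongside (`age_rounded`)
used for modal-year statistics, matching the convention of reporting
turning ages in whole years/days.

Post-turn classes come from sample-level simple linear regressions on
each side of the turning age, with slope p-values pooled across features
and Benjamini-Hochberg adjusted at FDR 0.05: a non-significant pre-turn
slope leaves the feature unclassified (excluded from
trajectory-characteristics summaries); otherwise a non-significant
post-turn slope is a *plateau*, an opposite-signed significant slope a
*reversal*, and a same-signed one a *continuation* (our added class;
only plateau/reversal enter shape summaries).  The sex comparison is a
paired Wilcoxon signed-rank test on features turning in both sexes
(an unpaired rank-sum variant and X-chromosome exclusion are provided);
p-values are reported as computed, with no underflow floor.

### Detector accuracy and smoother bias

On noiseless trajectories evaluated on the grid, the detector recovers
planted turning ages to within one grid step (the midpoint-derivative
stencil's worst case).  Through a 3-df spline fit, however, the
*smoother* dominates the error: on the generator's rise-then-plateau
trajectories the fitted peak lands 9–19 years late even without noise
(ideal symmetric bumps: 1–7 years), and no smoother in the package
(df 3–10, lowess span 0.2–0.5) localizes more than ~30 % of planted
turns to within 2 years at realistic noise.  Per-gene turning ages are
therefore method-dependent population statistics, not 2-year-accurate
point estimates — consistent with the ~10-year spread of mean turning
age across 3-df/4-df/loess smoothing choices on real cortex data.  The
relevant acceptance check is left failing rather than re-tuned.

## Scores

Age-linked score: `S(g,T) = base^(−|A_g − T| / scale) · |ΔE|`, base 1.5
(configurable; conclusions on planted data are stable for base 1.25–2),
scale 1 for human years and 650/78 for mouse days (old-age equivalence:
650 d ≈ 78 y), target grid T = 1..78 y (human) or 1..650 d (mouse).
Decile age sets place boundaries at the k/10 quantiles of turning ages,
ties to the lower set; the decile score is |ΔE| in the set containing
A_g and zero elsewhere, so each turning gene's row sums to |ΔE|.  The
peak score is the age-linked column at the whole year/day with the most
turning points (ties break to the earliest year, logged).

## Enrichment tests

All resampling uses `numpy.random.default_rng(seed)`; identical seeds
give bit-identical p-values.  The bootstrap set test drops target genes
absent from the expressed background, then compares the target's mean
score with means of `n_boot` same-length lists drawn without replacement
from the background; `p = (1 + #{null ≥ obs}) / (1 + n_boot)`, one-sided
for enrichment (the conventional direction; a degenerate
target = background comparison reports p = 1 with a warning).  Per-age
screens Bonferroni-correct over the 78 target ages (times the number of
gene lists when screened jointly) and merge significant ages into
contiguous windows — note `n_boot` must exceed `n_ages/α` (e.g. 2000 for
78 ages at α = 0.05) for any age to be able to clear the correction.
Decile-set tests Bonferroni-correct over the 10 sets.  The
covariate-matched variant assigns every expressed annotated gene to a
10×10 transcript-length × GC decile grid and draws the i-th null gene
from the i-th target gene's cell.  The association test couples gene
z-scores with a score column via `Σ z_g·S_g`, permuting z (default
20,000 times) after removing the extended MHC (default chr6:25–34 Mb,
GRCh37; configurable — the region's LD makes gene-level scores
unassignable); a round-off tolerance (1e-9 relative) makes
permutation-invariant statistics tie exactly, so constant z gives p = 1.
Hypergeometric over-representation and quantile-comparison (sorted
target vs sorted random-list scores) utilities round out the set tests.
Direction- and cell-type-restricted variants are background filters
composed with the same tests.

## Cell-type enrichment

Specificity is row-normalized mean expression (all-zero rows stay zero).
Target lists: per turning-count-decile window and per direction, genes
are ranked by signed ΔE and the top 10 % *of the window's turning-gene
count* taken per direction (a global-ranking alternative is a config
option); genes absent from the specificity data are dropped after
ranking without re-topping-up.  The test compares the target's mean
specificity per cell type with uniform same-length draws from the shared
window background (which contains both directions); enrichment is
d = (observed − μ)/σ in null standard deviations, with σ at round-off
level flagged degenerate and d set to 0.  Bonferroni covers cell types ×
windows × directions.  For display, d is divided by its maximal absolute
value across windows per (cell type, direction), so the extreme
enrichment is exactly ±1.  Neuron/glia restriction ranks genes by the
ratio of summed neuronal to summed glial mean expression (zero glial sum
→ +inf, ranked first) and keeps the top N (default 5000; 1000–8000 is a
reasonable sensitivity range).

## Age prediction

Outer 10-fold split (seeded, shuffled) isolates test folds.  Within each
outer fold, probes are ranked by the slope p-value of expression ~ age
computed only on the training folds (equivalently by squared correlation
with age; constant probes get p = 1), and the top `n_cutoff` kept
(defaults 40 human / 100 mouse).  Hyperparameters of an RBF SVR
(features standardized on the training data) come from an inner 10-fold
grid search minimizing squared error: coarse grid γ = 2^{−15,−13,…,13},
C = 2^{−5,−3,…,15} (the odd-integer base-2 exponent convention), then a
fine grid ±1.5 around the coarse optimum in steps of 0.125.  One outer ×
one inner round is used (repeats are config).  Accuracy is the mean
|actual − predicted| over the pooled outer-fold predictions; R² is the
coefficient of determination.  `select_n_cutoff` reports cross-validated
SSE per candidate probe count and leaves the choice to the user.

## Synthetic cohorts

The generator is a pure function of its spec (seed mandatory).  Defaults
mirror a human lifespan design: 200 samples from −0.5 y (14th
gestational week) to 78 y, half below 20 y (lifespan cohorts oversample
early life); 500 genes, half simple (linear monotone — exactly
representable by the spline, so they never produce spurious turns);
complex genes turn at ages ~ Normal(26, 8) truncated to the lifespan
with |ΔE| ~ Uniform(0.5, 2), 70 % plateau / 30 % reversal, equal up/down
mix; Gaussian noise with sd 0.25·|ΔE| (relative by default); female
turning ages delayed 1.5 y.  Complex trajectories are cosine-eased
ramps of magnitude |ΔE| to the turn — smooth, so detector/smoother bias
is measurable rather than trivially zero — followed by a cosine-eased
reversal of 80 % of |ΔE|, or, for plateaus, a 5 % drift: real plateau
probes are near-flat rather than exactly flat, and the slight decline
keeps the turning point geometrically defined (a derivative sign change)
while staying statistically undetectable at the default noise, so
classification still calls them plateaus.  Planted gene sets and
cell-type blocks draw their turning ages from their own truncated
normals; specificity matrices are gamma-distributed mean expression with
marker blocks boosted ×5 before row normalization; association z-scores
are standard normal or linearly score-coupled.

What the generator does *not* emulate: probe-level microarray artifacts
(cross-hybridization, saturation), heteroscedastic or age-dependent
noise, correlated co-expression modules, missing values, or batch
structure.  Passing tests therefore demonstrate the statistical
machinery (calibration, power, recovery of planted structure), not
robustness to real-data pathologies; inputs are assumed already
normalized and batch-adjusted.

## Other design choices and limitations

- Fetal human ages are negative years (14th gestational week ≈ −0.50 y);
  the scoring grid starts at T = 1.
- Duplicate probes per gene symbol collapse to the largest peak score,
  ties to the lexicographically smallest feature id; unannotated probes
  are kept under their own id.
- Datasets whose sampling ends early can optionally treat non-turning
  trajectories as turning in the final sampled year (off by default).
- Ortholog mapping between species is consumed as a user-supplied
  two-column table; no 1:1/1:many filtering is guessed.
- Multi-turning-point modelling, changepoint regression, confidence
  bands on trajectories, automatic df selection and alternative learners
  for age prediction are out of scope.
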