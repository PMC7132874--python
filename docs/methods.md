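# Methods

## The omnibus informativeness test

Given per-feature association p-values p₁…p_m and a candidate covariate
x₁…x_m, the test asks whether p and x are dependent. Under sparse signal,
dependence is concentrated in the extreme low-p tail, and it may be
non-monotone in x (e.g. signal enriched at both methylation extremes), so a
single rank-correlation statistic has little power. The omnibus statistic
therefore pools evidence over a grid of views of the data:

1. **Dichotomization.** For each cutoff quantile q ∈ {0.001, 0.005, 0.01,
   0.05, 0.1, 0.2}, P⁽ⁱ⁾ = 1{p ≤ quantile_q(p)}. Cutoffs are quantiles of
   the *observed* p-values, not absolute thresholds, so the view adapts to
   the overall signal level. The quantile is the linear-interpolation
   (type 7) definition; ties at the cutoff fall into the low class. Both
   choices are arbitrary but fixed for reproducibility.
2. **Categorization.** A continuous covariate is sliced at its
   {1/n, …, (n−1)/n} quantiles for n ∈ {2, 4, 8, 16, 32}, giving
   right-closed equal-size categories. Duplicate breakpoints (heavy ties)
   merge the affected categories; a slicing that collapses below two
   categories is skipped. A categorical covariate is used as-is.
3. **Scoring.** Each 2×L table is scored by the Pearson χ² test (no
   continuity correction) and, when the categories are ordered slices of a
   continuous covariate, also by the two-sided Cochran–Armitage trend test
   with integer scores 1…L (recovering power under monotone dependence).
   Scores are −log p, computed through `logsf` so extreme dependence does
   not underflow. Degenerate tables (empty low class, single category,
   zero trend variance) score 0: the max stays well-defined and the rule
   is identical for observed and permuted data, which is all permutation
   validity requires.
4. **Max and permutation.** t° is the maximum score over the grid. The
   covariate vector is permuted K times (equivalent to permuting p under
   the exchangeable null, and cheaper to bookkeep); the same grid statistic
   is recomputed, and pval = (1 + #{t₍k₎ᵖ ≥ t°})/(1 + K), so the smallest
   attainable p-value is 1/(1+K). K defaults to 999; the evaluation
   harness uses K = 199, which resolves rejection at the 0.05 level.

Because the max is a monotone function of the component scores, the
permutation p-value is invariant to the base of the logarithm.

**Null-independence variant.** The same machinery restricted to p > 0.5
(dominantly null features) with evenly spread cutoff quantiles {0.1, 0.2,
0.4, 0.6, 0.8, 0.9} tests the complementary requirement that the covariate
be independent of p under the null. In practice a covariate should be
significant in the informativeness test and non-significant here.

**Exchangeability.** Neighbouring CpGs are correlated, which breaks the
permutation null. `decorrelate_subsample` orders features by genomic
position and takes every s-th one, growing s until the lag-1
autocorrelation of the retained sequence is below 0.05 in absolute value,
subject to a floor of 5,000 retained features (both configurable; the
reference analysis states only "near zero" autocorrelation).

**Implementation note.** Dichotomized classes are prefixes of the p-sorted
order and category sizes are permutation-invariant, so expected counts, χ²
scale factors and trend variances are precomputed once; a permutation only
re-bins the low-p features, and −log p transforms are applied vectorized
over the whole permutation batch.

## Covariates

Statistical covariates are computed per feature from the Beta-value matrix
(M = log₂(β/(1−β)) where noted): mean, sd.b, sd.m, mad (median absolute
deviation × 1.4826, the normal-consistency constant), dip (Hartigan's dip
statistic), precision (1/(mean(1−mean)/sd² − 1), the inverse concentration
of a moment-matched beta distribution; undefined and flagged missing when
sd² ≥ mean(1−mean)), direction (sign of the marginal per-feature regression
slope of M on the phenotype; a zero slope counts as positive), and icc.b /
icc.m (one-way ANOVA ICC(1) with the standard unbalanced-design group-size
correction k₀; reported untruncated since downstream use only needs
ordering). Beta-values are clipped to [1e−6, 1−1e−6] upstream so the logit
is finite. Annotation covariates come from the 450K-manifest dialect;
multi-valued gene-region entries collapse to the first listed and absent
annotation becomes Non_gene. Missing covariate values are excluded
pairwise at test time, never imputed.

For regression-based procedures, continuous covariates are expanded in a
natural cubic spline basis with 6 degrees of freedom (truncated-power
construction, boundary knots at the data range, interior knots at equally
spaced quantiles; the df degrades gracefully when there are fewer distinct
values), categorical covariates in treatment indicators with the first
level as reference.

### The dip statistic

No dip implementation is available in the dependency set, so the package
ships its own exact one. The dip of a sample is
min over unimodal cdfs G of sup_x |F_n(x) − G(x)|, where a unimodal cdf is
convex up to its mode and concave after (one atom allowed at the mode).
The implementation bisects on the tube half-width d and decides whether a
unimodal cdf fits inside [F_n − d, F_n + d]: for every candidate mode
position, the left prefix admits an increasing convex function in the tube
iff 2d is at least the maximal gap between the ecdf and its greatest convex
minorant (mirrored with the least concave majorant on the right), and the
two pieces must join monotonically — the minimal attainable end value of
the convex piece (an upper envelope of supporting lines, with the steepest
slope at each knot found on the lower hull of the tube ceiling) must not
exceed the maximal attainable start value of the concave piece. When the
junction is slack at the minorant/majorant bound — the typical unimodal
sample — no bisection is needed at all. The test suite verifies exact
agreement (1e−9) with an independent linear-programming oracle that
minimizes the sup-distance over piecewise-linear unimodal envelopes
directly. Estimates are floored at 1/(2n), the attainable minimum.

## FDR procedures

- **BH**: step-up; adjusted values are the usual monotone min(m·p₍ⱼ₎/j).
- **ST**: Storey's q-value. π₀̂(λ) = #{p > λ}/(m(1−λ)) on the grid λ =
  0.05, 0.10, …, 0.95; a cubic polynomial smoother is evaluated at the
  largest λ and clamped to [0, 1] (the reference implementation's
  smoother-at-max-λ rule; its exact spline settings are not documented, so
  a cubic polynomial is used — deterministic and close to a df-3 smoothing
  spline on a 19-point grid). q = π₀̂ × BH-adjusted, so ST never rejects
  less than BH.
- **BL**: the covariate-conditional version. For every λ in the same grid,
  the indicator 1{p > λ} is regressed on the encoded covariate basis by
  least squares; fitted values scaled by 1/(1−λ) and truncated to [0, 1]
  give π₀̂_λ(xᵢ), smoothed over λ by the same cubic-at-max-λ rule. The
  final π₀̂(xᵢ) scales the feature's BH-adjusted value. With a constant
  (or unusable) covariate the regression collapses to its intercept and
  the procedure reduces exactly to the scalar Storey-type estimate.

A known small-sample property of BL: the 1/(1−λ) factor amplifies
regression noise at large λ, and truncation at 1 converts that variance
into a downward bias of π₀̂ — anti-conservative in expectation, vanishing
as 1/√m. At a few thousand features the realized mean FDP can sit a point
above the target; at the reference template size (m = 11,808) all three
procedures control the target in the evaluation harness, which therefore
runs its FDR-control check at that size. External covariate-adaptive
methods (IHW, CAMT, AdaPT, FDRreg) are deliberately not re-implemented;
their exported per-feature adjusted values can be ingested from TSV.

## Simulation designs

**P-value level** (for evaluating the omnibus test): m = 10,000 hypotheses;
covariate x ~ N(0,1) (continuous) or uniform on {1…5} (categorical);
π₀ᵢ = expit(η₀ + c·xᵢ) on the standardized covariate, with x² replacing x
for the non-monotone design (the analyst still sees x); η₀ ∈ {3.5, 2.5,
1.5} gives expected signal fractions of 3%, 8%, 18% at c = 0; c ∈ {0,
0.25, 0.375} spans no/weak/moderate dependence; zᵢ ~ N(0,1) under the
null and N(2.68, 1) under the alternative; p = 1 − Φ(z).

**Methylation level** (for evaluating FDR procedures): a synthetic template
replaces the real control-group template so no download is needed.
Baseline per-feature M-values are drawn from the bimodal methylation
landscape — 45% hypomethylated around M = −2.5, 45% hypermethylated around
+2.5 (sd 0.8), 10% intermediate N(0,1) — with per-feature noise scale
uniform on [0.4, 0.8] (M-value units, the typical within-group spread of
array data) and sample-level AR(1) noise along the feature order with
coefficient 0.75, so neighbouring features correlate across samples as
neighbouring CpGs do on arrays. Two groups of n = 80 samples; differential
status from the same logistic π₀ model with c ∈ {0, 1, 1.5} (x independent
normal, or AR(1) with coefficient 0.75 along the genome when signals
should cluster — unit innovation variance, matching the reference
generator); differential features get f ∈ {0.27, 0.33, 0.45} added to
group-2 M-values; per-feature p-values from the two-group equal-variance
regression on M-values (identical to the classical t test, asserted in the
suite). With f = 0 the truth vector is all-null by definition.

What the generator does *not* emulate: cell-type heterogeneity, batch
effects and other confounders (so no surrogate-variable step is simulated),
probe-type intensity bias, heavy-tailed outliers, and the irregular
spacing/block structure of real CpG correlation (the AR(1) field is
homogeneous). Passing benchmarks therefore demonstrate the statistical
mechanics of the procedures under the assumed generative model, not
robustness to those real-data artefacts.

## Evaluation harness and problem sizes

Type I error of the omnibus test is assessed at m = 2,000 with K = 199 and
a few hundred replicates — size is scale-free, so the smaller m only adds
Monte-Carlo noise. Power orderings (omnibus vs Spearman/Kruskal–Wallis)
are assessed at the design's native m = 10,000, where the sparse-signal
cells have resolvable power; at m = 2,000 every test in those cells is
near-powerless and no ordering can be established. FDR control is assessed
at the reference template size m = 11,808 with 100 replicates per cell
(see the BL note above); the acceptance script's BH-only check runs at
m = 2,000, where BH is comfortably controlled. Per-replicate seeds derive
from a master seed by fixed offsets so any cell can be re-run
independently.

## Known limitations

- The omnibus p-value is granular (multiples of 1/(1+K)); with K = 199 the
  smallest attainable value is 0.005.
- The decorrelation subsampler only targets lag-1 autocorrelation; strong
  longer-range dependence can survive thinning.
- BL's small-m anti-conservativeness is inherent to π₀ regression with
  truncation; users with a few thousand features should prefer ST/BH or a
  coarser basis.
- The dip computation is exact but iterative (worst case O(K log K) hull
  passes per bisection step); covariate tables on hundreds of thousands of
  features will feel it.
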