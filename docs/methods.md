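# Methods

`exprdist` characterizes the per-gene distribution of log-scale expression
measurements from microarray studies: which univariate families (if any) fit
individual genes, and what systematic structure the per-gene moments show.
This note records the statistical procedures, the tunable parameters and
their defaults, what the synthetic generator does and does not emulate, and
the numerical choices that were genuinely open.

## Data model and screening

Input is a gene × sample matrix of log2 expression (single-color platforms;
strictly positive after GCRMA-style normalization) or of log ratios against
a common reference pool (two-color platforms; may be negative). Analysis of
distributional shape only makes sense for genes whose location was not
shifted by the experimental conditions, so each gene is first tested across
conditions with the Kruskal–Wallis rank test (tie-corrected mid-ranks,
chi-square reference with k−1 df). Genes with p > 0.1 are retained; the
deliberately liberal cutoff trades a 10% loss of truly unaffected genes for
high confidence that retained genes are condition-stable. With a single
condition the screen is undefined and everything is retained with a warning.

Genes are further stratified against a noise floor — mean log2 expression
above 6 (single-color) or |mean log ratio| above 0.05 (two-color), both
strict inequalities — below which measurements behave like optical or ratio
noise with inflated CV, skewness and kurtosis. Signal-stratum genes feed the
trend fits; the noise stratum is summarized descriptively with loess.

For two-color data an "active" seed gene set can be expanded by Pearson
correlation: any gene whose two-sided correlation p-value (t transform,
n−2 df) with at least one seed gene falls below 1e-5 joins the set.

Cross-batch quantile normalization forces every sample onto the mean of the
order statistics pooled over all batches (mean, not median, reference
quantiles); ties receive the mean of the tied reference quantiles via
average ranks. The transform is idempotent and equalizes all column means.

## Distribution fitting

Eight candidate families: normal, lognormal, logistic, log-logistic,
Weibull, extreme value, gamma, Pareto. The five positive-support families
are unavailable for log-ratio data. Fits are maximum likelihood:

* normal — closed form with the 1/n (plug-in) sigma;
* lognormal / log-logistic — exactly the normal / logistic fit of the
  logged values (a parameter identity asserted in tests);
* gamma — Newton iteration on the shape profile log-likelihood
  ln k − ψ(k) = ln x̄ − mean(ln x), initialized at the standard
  (3 − s + √((s−3)² + 24s))/(12s) approximation;
* Pareto — closed form with x̂ₘ = min(x), α̂ = n / Σ ln(xᵢ/x̂ₘ);
* logistic, Weibull (two-parameter, location 0), Gumbel — numerical MLE.

The extreme value family is the minimum-type Gumbel by default (the
convention of the fitting routines used for the original analyses of this
kind); the maximum type is available via `max_type=True`. Candidate families
are fitted directly to the supplied log-scale values: single-color log
expression is strictly positive, so the positive-support families apply to
it without re-exponentiation.

Normal mixtures are fitted by EM with k-quantile-jitter initialization,
5 restarts, tolerance 1e-8 on the log-likelihood, a 100-iteration cap and a
component-sd floor of 1e-6 of the data sd; the per-iteration log-likelihood
path is retained and checked monotone. k = 1 reduces exactly to the normal
MLE.

## Goodness of fit with estimated parameters

Estimating parameters from the data under test makes textbook KS/AD critical
values invalid (the composite-null problem). Calibration is a Lilliefors-
style parametric bootstrap: fit θ̂, compute the observed statistic, then B
times simulate n draws from F(θ̂), refit, recompute; the p-value is
(1 + #{bootstrap ≥ observed}) / (B + 1), never exactly zero, with rejection
flags at the 90% and 95% levels. B defaults to 1000. One mechanism covers
all families: published critical-value tables for specific families are the
limit of the same bootstrap, so they are not special-cased (a hook for
user-supplied tables is unnecessary when B is cheap). For location-scale
pivotal families (normal, lognormal via logs, Pareto via exponentials) the
refitted statistic's null distribution does not depend on θ̂, so the
bootstrap is simulated directly in pivotal form — algebraically identical to
simulate-and-refit, but vectorized. Per-gene bootstrap streams derive from
(master seed, gene index), making batch results reproducible and independent
of iteration order.

The AD statistic A² = −n − (1/n) Σ (2i−1)[ln F(x₍ᵢ₎) + ln(1−F(x₍ₙ₊₁₋ᵢ₎))]
weights the tails more than KS's sup-distance D, and rejects at least as
often against skewed alternatives (asserted on gamma-shape-2 data).

Batch testing over a gene set reports, per family, the fraction of genes
rejected at 95% and the fraction of genes with at least one family not
rejected; positive-support families are recorded as NA for log-ratio
matrices and for individual genes violating the support.

### Chi-square mixture comparison

Comparing a single normal against a 3-component mixture uses a chi-square
GOF on counts in equal-count cells at sample quantiles (expected counts
n/bins under the fitted model; default bins = min(max(4, n/10), 20)). The
df = bins − 1 − params reference requires the parameters to be estimated
from the binned counts themselves: with ungrouped EM estimates the statistic
is stochastically larger (Chernoff–Lehmann), which we measured as ~11
percentage points of excess rejection for k=3 on truly normal genes. The
mixture is therefore refitted to the counts by grouped multinomial ML
(L-BFGS-B on softmax weights, means, log sds, initialized from EM) — the
grouped-data approach of classical binned mixture analysis. A generic
equal-probability-bin chi-square against any fitted density is also provided.

## Moments

Product moments use plug-in (1/n) estimators, not bias-corrected ones, so
the Pearson attainability bound K ≥ S² + 1 holds algebraically for every
sample and the normal reference is (S, K) = (0, 3); kurtosis is reported
raw, not excess. This matches overlaying the population bound on per-gene
sample points, which only plug-in estimators guarantee.

Sample L-moments are Hosking's unbiased PWM estimators
(b_r = (1/n) Σ x₍ᵢ₎ C(i−1,r)/C(n−1,r); ℓ1 = b0, ℓ2 = 2b1 − b0, …), with
ratios τ3 = ℓ3/ℓ2 and τ4 = ℓ4/ℓ2. Unbiasedness holds for the ℓ_r, not for
the ratios, and the population bound τ4 ≥ (5τ3² − 1)/4 is **not** an
algebraic sample property of these estimators: tiny tied samples
([0,0,0,1,1] → τ4 = −0.67) and two-cluster samples at any n violate it. It
is therefore checked distributionally — across 10^5 samples of size 50 from
mixed continuous families no violation occurs — rather than asserted
sample-wise as the product-moment bound is.

Theoretical (τ3, τ4) loci for the L-moment ratio diagram: GLO and GPA use
their closed forms (τ4 = (1+5τ3²)/6 and τ3(1+5τ3)/(5+τ3)); GEV uses the
closed form in the shape parameter with the shape solved by Brent's method;
GNO and PE3 are computed by Gauss–Legendre quadrature (4096 nodes) of the
quantile function against shifted Legendre polynomials, again inverting
shape→τ3 by Brent — the published polynomial approximations are kept only as
an independent cross-check (agreement ≤ 2e-3). Point families: EXP (1/3,
1/6) and UNI (0, 0) exactly; NOR, GUM, RAY by quadrature.

## Trend models

Over the signal stratum, ordinary least squares fits log10 CV = a + b·mean
(genes with non-positive CV excluded and counted) and K = c0 + c1 S + c2 S²
(bound violations counted; zero by construction of the plug-in estimators).
Base-10 logs reproduce the magnitude of the observed intercepts for
single-color data. Coefficients are reported with plain OLS standard errors
even though the residuals are heteroscedastic and non-normal; the
diagnostics (Pearson ρ of |residuals| against each covariate, plus a
bootstrap AD normality p-value for the residuals) quantify the violation
instead of correcting it, and the F-test p-value is reported to machine
precision. Loess for the noise stratum is local linear regression with
tricube weights (span 0.75, no robustness iterations), evaluated on an even
grid. The Spearman mean–sd correlation uses mid-rank ties.

## Synthetic data generator

The generator produces matrices with the moment structure described above,
plus a ground-truth table, so every stage is testable without downloads.
Defaults emulate a single-color study: 69 arrays in 3 condition groups,
means uniform on (6, 14) — the post-noise-floor range — CV following
log10 CV = −2.10 − 0.22·mean (the brain-tissue line) with lognormal jitter
of 0.1 in log10 units, 30% of genes in a noise stratum (means uniform on
(2, 6), CV inflated 3×), and 40% condition-affected genes.

Choices the observed trends do not constrain, fixed once here:

* **Scatter model.** Only the fitted trend lines are observed; the uniform
  mean distribution, the 0.1-dex CV jitter and the 3× noise-stratum CV
  inflation are stand-ins chosen to look like the published scatter plots.
* **Affected genes** get location-only shifts: condition j (of J) is offset
  by effect·(j/(J−1) − 1/2), so the extreme conditions differ by exactly the
  effect size (by default in units of the gene's sd). Real condition effects
  also change shape; that is out of scope.
* **Mixture-mode genes** draw from 2–3 normal components at ±1.5 sd (or
  −2, 0, +2 sd) around the gene mean with component sd of half the gene sd.
* **Shape control.** With no kurtosis–skewness trend requested, each gene
  draws from a named family whose parameters are moment-matched to the
  gene's (mean, sd) — Weibull/log-logistic shapes solved from the CV by
  Brent's method, gamma/lognormal/Pareto in closed form. A named family then
  pins (S, K) jointly (a gamma always has K = 3 + 1.5 S²), so an arbitrary
  quadratic K(S) relation is unreachable by family mixing. When
  `kurt_skew_trend=(c0, c1, c2)` is set, genes instead use a cubic transform
  of a standard normal (Fleishman polynomial) that moment-matches mean, sd,
  S and K per gene: S ~ N(0, 0.6) truncated to ±1.3, and
  K = c0 + c1 S + c2 S² plus jitter. The jitter (sd 0.6) is truncated
  *symmetrically* to the feasible head-room above the cubic-normal
  boundary (K ≳ 1.90 + 1.65 S²), so E[K | S] stays exactly on the trend; the
  jitter magnitude reproduces R² ≈ 0.6 for the fitted quadratic, in the
  range seen in real tissues. Noise-stratum genes get a wider skew spread
  (2×) and extra positive kurtosis, again a stand-in.

**What passing tests show.** Trend-recovery tests demonstrate that the
pipeline's estimators recover the generating relationships; they do not
validate the generator against real arrays (no probe-level effects, spatial
artifacts, or condition-dependent shape changes are modeled). Recovery of
the kurtosis–skewness quadratic is run at 10^4 genes × 24 000 samples per
gene: plug-in skewness/kurtosis have O(1/n) bias whose constant is several
times the normal-theory value for the heavier-tailed cubic-normal genes, and
this n keeps that bias well inside the trend fit's standard errors (the OLS
SE floor is set by the population jitter, ≈ jitter/√G). The CV trend is
recovered already at n = 100, where the 0.1-dex jitter dominates all
small-sample effects.

## Degenerate inputs and numerical edges

Constant genes: flagged degenerate; sd = 0, skewness/kurtosis and L-moment
ratios NaN; fitting raises a degenerate-data error that batch routines
record as NA. Fitted cdf values of exactly 0 or 1 make the AD statistic +∞
(flagged, counts as maximal evidence against). Mean exactly at the noise
floor falls in the noise stratum. The KW test returns (H, p) = (0, 1) for
all-identical data. Quantile normalization of a single pooled sample is the
identity.

## Known limitations

* The bootstrap GOF at B = 1000 has p-value granularity 1/1001; rejection
  fractions inherit that discreteness.
* The chi-square approximation for the KW test is slightly conservative
  mid-range at group sizes around 10 (discrete rank statistic); the lower
  tail, where screening operates, is accurate to ~1%.
* OLS standard errors for the trend fits ignore the measured
  heteroscedasticity; they are reported as descriptive uncertainties only.
* The generator's noise stratum is a stand-in: real optical noise couples
  mean and variance differently than a scaled CV trend.
* Grouped-ML mixture fitting with k = 3 on unimodal genes sits on a
  boundary of the parameter space; its chi-square reference is adequate for
  comparing rejection fractions, not for per-gene p-value precision.
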