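# exprdist

Distribution characterization of microarray gene-expression data.

Many analysis methods for expression data — empirical-Bayes differential
expression, network inference, classifiers — lean on a distributional
assumption (usually normality of log expression) that is rarely checked.
`exprdist` is a pipeline for checking it: given a gene × sample matrix of
log2 expression (or two-color log ratios), it

1. **screens** out genes affected by the experimental conditions
   (Kruskal–Wallis across conditions, retaining genes with p > 0.1) and
   stratifies genes against a noise floor (mean log2 expression ≤ 6, or
   |mean log ratio| ≤ 0.05, behaves as measurement noise);
2. **fits** eight candidate families per gene by maximum likelihood —
   normal, lognormal, logistic, log-logistic, Weibull, extreme value,
   gamma, Pareto — and **tests** each with Kolmogorov–Smirnov and
   Anderson–Darling statistics calibrated by parametric bootstrap, the
   correct treatment when parameters are estimated from the data under test;
3. **summarizes** the per-gene moment structure: plug-in product moments
   (mean, SD, CV, skewness S, kurtosis K), Hosking sample L-moments
   (ℓ1, ℓ2, τ3, τ4), the linear trend of log10 CV on the mean, the
   quadratic trend K = c0 + c1·S + c2·S² (always above the theoretical
   bound K ≥ S² + 1), and the L-moment ratio diagram with theoretical
   curves for GEV, GLO, GNO, GPA, PE3 and the classical point families;
4. **compares** a single normal against a 3-component normal mixture per
   gene with a grouped-ML chi-square test.

A first-class synthetic-data generator emulates the moment structure of
normalized expression matrices (CV-vs-mean trend, kurtosis–skewness
quadratic, noise stratum, condition-affected and mixture-mode genes) with a
ground-truth table, so the whole pipeline is testable without any data
download. See `docs/methods.md` for the statistical details.

## Worked example

```python
from exprdist import (generate, screen_unaffected, noise_floor_filter,
                      moment_table, fit_log_cv_vs_mean, batch_gof)
from exprdist.synthetic import SyntheticSpec

spec = SyntheticSpec(n_genes=1000, n_samples=30,
                     condition_labels={"control": 10, "treated": 10, "recovery": 10},
                     noise_fraction=0.3, affected_fraction=0.4, seed=1)
matrix, truth = generate(spec)

screen = screen_unaffected(matrix, spec.condition_map(), alpha=0.1)
print(f"retained {screen.table.retained.sum()}/1000 genes")

table = moment_table(matrix)
signal = noise_floor_filter(table["mean"]).signal.to_numpy()
fit = fit_log_cv_vs_mean(table, signal)
print("log10 CV = {:.2f} {:+.2f} * mean   (R^2 = {:.2f})".format(
    *fit.coefficients, fit.r_squared))
```

prints

```
retained 712/1000 genes
log10 CV = -2.09 -0.22 * mean   (R^2 = 0.95)
```

About 90% of the truly unaffected genes survive the p > 0.1 screen (the
cutoff's designed retention rate) while most condition-affected genes are
removed, and the fitted CV trend recovers the generating line: the
coefficient of variation of log expression falls by about 0.22 dex per
log2 unit of mean expression. `examples/` contains one short script per
capability (screening, distribution testing, moment trends, the L-moment
diagram, the mixture comparison), each printing the numbers it computes and
what they mean. A thin CLI mirrors the stages:

```sh
exprdist simulate --config spec.yaml --out study
exprdist screen study.matrix.tsv study.conditions.tsv --alpha 0.1 --out screen.tsv
exprdist gof study.matrix.tsv --families normal,logistic --stat ad -B 1000 --seed 1 --out gof.tsv
exprdist moments study.matrix.tsv --out study
exprdist trends study.moments.tsv --out study
```

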