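"""Fit candidate families to genes and test them with bootstrap-calibrated
Anderson-Darling statistics.

Parameters are estimated from the same data being tested (a composite
null), so critical values come from a parametric bootstrap: simulate from
the fitted distribution, refit, recompute the statistic, repeat.
"""

from exprdist import DistFamily, batch_gof, fit_mle, generate
from exprdist.synthetic import SyntheticSpec

spec = SyntheticSpec(
    n_genes=60, n_samples=69, noise_fraction=0.0, affected_fraction=0.0,
    condition_labels={"all": 69}, seed=2,
)
matrix, _ = generate(spec)

gene = matrix.gene_ids[0]
fit = fit_mle(matrix.values[0], DistFamily.NORMAL)
print(f"{gene}: normal MLE mu={fit.params['mu']:.3f} sigma={fit.params['sigma']:.3f} "
      f"loglik={fit.loglik:.1f}")

summary, table = batch_gof(
    matrix, matrix.gene_ids,
    families=["normal", "logistic", "extreme_value"],
    statistic_type="ad", B=500, seed=11,
)
print("\nfraction of genes rejected at the 95% level (AD, B=500):")
print(summary.per_family.round(3).to_string())
print(f"at least one family not rejected: {summary.frac_at_least_one_not_rejected:.3f}")
print()
print("These genes are generated normal, so the normal row shows the ~5% nominal")
print("type-I rate while the misspecified families are rejected far more often.")
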