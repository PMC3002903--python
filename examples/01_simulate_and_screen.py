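"""Simulate a small expression study and screen for condition-unaffected genes.

Generates a 1000-gene x 30-array study (3 conditions), runs the per-gene
Kruskal-Wallis screen at the liberal p > 0.1 cutoff, and stratifies genes
against the mean-expression noise floor of 6 (log2 units).
"""

from exprdist import generate, noise_floor_filter, screen_unaffected
from exprdist.synthetic import SyntheticSpec

spec = SyntheticSpec(
    n_genes=1000,
    n_samples=30,
    condition_labels={"control": 10, "treated": 10, "recovery": 10},
    noise_fraction=0.3,
    affected_fraction=0.4,
    seed=1,
)
matrix, truth = generate(spec)

screen = screen_unaffected(matrix, spec.condition_map(), alpha=0.1)
strata = noise_floor_filter(matrix.values.mean(axis=1), mode="log_expression")

n_ret = screen.table.retained.sum()
print(f"retained (KW p > 0.1): {n_ret}/{spec.n_genes} genes")
print(f"  among truly unaffected genes: {screen.table.retained[~truth.affected].mean():.2f}")
print(f"  among truly affected genes:   {screen.table.retained[truth.affected].mean():.2f}")
print(f"noise stratum (mean <= 6): {int(strata.noise.sum())} genes "
      f"(generator placed {int(truth.noise.sum())})")
print()
print("Retention is ~0.9 for unaffected genes by construction of the 0.1 cutoff;")
print("affected genes are mostly screened out, and the noise stratum is excluded")
print("from all downstream trend fits.")
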