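"""Does a 3-component normal mixture fit per-gene expression better than a
single normal?

For each gene the data are binned at sample quantiles and both models are
fitted to the counts by grouped multinomial ML; the chi-square GOF with
df = bins - 1 - params then compares rejection fractions.  On unimodal
genes the mixture buys nothing; on true mixture-mode genes it does.
"""

import numpy as np

from exprdist import fit_mixture_em, generate, mixture_chisq_gof
from exprdist.synthetic import SyntheticSpec

rng = np.random.default_rng(5)

spec = SyntheticSpec(
    n_genes=80, n_samples=155, mode="log_ratio", noise_fraction=0.0,
    affected_fraction=0.0, mixture_fraction=0.5, condition_labels={"f2": 155},
    family_weights={"normal": 1.0}, cv_trend=(0.57, -1.67), seed=5,
)
matrix, truth = generate(spec)

rej = {1: [0, 0], 3: [0, 0]}  # k -> [unimodal, mixture-mode] rejection counts
counts = [int((~truth.mixture).sum()), int(truth.mixture.sum())]
for g in range(spec.n_genes):
    is_mix = int(truth.mixture.iloc[g])
    for k in (1, 3):
        rej[k][is_mix] += mixture_chisq_gof(matrix.values[g], k, seed=g).reject_95

print("chi-square rejection fractions at the 95% level:")
print(f"  unimodal genes  (n={counts[0]}):  k=1 {rej[1][0]/counts[0]:.2f}   "
      f"k=3 {rej[3][0]/counts[0]:.2f}")
print(f"  mixture genes   (n={counts[1]}):  k=1 {rej[1][1]/counts[1]:.2f}   "
      f"k=3 {rej[3][1]/counts[1]:.2f}")

x = matrix.values[np.where(truth.mixture)[0][0]]
em = fit_mixture_em(x, 3, seed=0)
print("\nEM fit of one mixture-mode gene (k=3):")
print("  weights:", np.round(em.weights, 2), " means:", np.round(em.means, 2))
print()
print("For unimodal genes k=3 shows no improvement over k=1 (both near the")
print("nominal 5%); genuine mixture-mode genes reject the single normal.")
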