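"""Fitting with imputed parental genotype sums.

When parents are unobserved, the sum of parental dosages can be replaced by
its posterior expectation given the two sibling genotypes under
Hardy-Weinberg priors.  This script compares estimates from true parental
sums against estimates from single-SNP imputed sums on the same cohort.
"""

import numpy as np

import parsec as P

valid = P.validate_parameters(P.FULL_SETTING)
rng = np.random.default_rng(11)
cohort = P.simulate_families(800, 500, seed=rng)
phenos = P.simulate_phenotypes(cohort, valid, seed=rng)

res_true = P.fit(cohort, phenos)
res_imp = P.fit(cohort.with_imputed_parents(), phenos)

print("posterior E[parent sum | sibs] examples at p = 0.3:")
for g1, g2 in [(0, 0), (0, 2), (1, 1), (2, 2)]:
    print(f"  sibs ({g1},{g2}) -> {P.impute_parental_sum(g1, g2, 0.3):.3f}")
print()
print(f"{'parameter':18s} {'truth':>7s} {'true parents':>13s} {'imputed':>9s}")
for name, t, a, b in zip(
    P.PARAM_NAMES,
    P.FULL_SETTING.to_array(),
    res_true.theta.to_array(),
    res_imp.theta.to_array(),
):
    print(f"{name:18s} {t:7.3f} {a:13.3f} {b:9.3f}")
print()
print("Imputation shrinks the parental-sum contrast (only two siblings inform")
print("it), so indirect-effect components are attenuated relative to fits on")
print("observed parental sums — the reason the estimator prefers true sums.")
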