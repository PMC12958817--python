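"""Simulate a cohort and estimate heritability with genomic REML.

Run: python examples/01_simulate_and_heritability.py
"""
import numpy as np

from stressqtl.simulate import preset, simulate_cohort
from stressqtl.varcomp import compute_grm, design_from_table, fit_univariate

cohort = simulate_cohort(preset("cl_cnur"), seed=1)
ph = cohort.phenotypes
print(f"cohort: {len(ph)} pigs, {cohort.genotypes.dosages.shape[1]} markers")
print(f"QTL marker: {cohort.truth.qtl_marker} "
      f"(sample MAF {cohort.genotypes.minor_allele_frequencies()[cohort.truth.qtl_index]:.3f})")

y = np.log(ph["CL_IS"].to_numpy(float))          # hair cortisol, IS phase, log scale
X, names = design_from_table(ph, factors=["batch"], covariates=["age_entry"])
grm = compute_grm(cohort.genotypes, method="standardized")

fit = fit_univariate(y, X, grm, pen=ph["pen"].to_numpy(), fixed_names=names)
print(f"\nh2 = {fit.h2:.3f} (SE {fit.h2_se:.3f}), converged={fit.converged}")
for k, v in fit.variances.items():
    print(f"  var[{k}] = {v:.4f} (SE {fit.variance_se[k]:.4f})")
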