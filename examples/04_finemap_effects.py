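"""Fine mapping around the QTL: allele-substitution effect, percent change
on the hormone scale, LD with a neighbour, and company-nested effects.

Run: python examples/04_finemap_effects.py
"""
import numpy as np

from stressqtl.simulate import preset, simulate_cohort
from stressqtl.varcomp import compute_grm
from stressqtl.finemap import (
    allele_substitution_effect, effect_by_group, ld_r2, percent_reduction,
)

cohort = simulate_cohort(preset("cl_cnur"), seed=1)
ph = cohort.phenotypes
y = np.log(ph["CL_IS"].to_numpy(float))
G = cohort.genotypes
grm = compute_grm(G, method="standardized")
qidx = cohort.truth.qtl_index
qid = G.marker_map["id"].iloc[qidx]
dq = G.dosage_float()[:, qidx]

eff = allele_substitution_effect(y, dq, None, grm, pen=ph["pen"].to_numpy(),
                                 marker_id=qid)
print(f"{qid}: beta = {eff.beta_log:.3f} +/- {eff.se_log:.3f} (log scale), "
      f"{eff.beta_psd:.2f} PSD, p = {eff.p_value:.2e}, MAF = {eff.maf:.3f}")
print(f"per-copy change on the hormone scale: {percent_reduction(eff.beta_log):.1f}% reduction")

neighbour = G.marker_map["id"].iloc[qidx + 1]
pair = ld_r2(dq, G.dosage_float()[:, qidx + 1], qid, neighbour)
print(f"LD with {neighbour}: r2 = {pair.r2:.2f}")

res = effect_by_group(y, dq, ph["company"].to_numpy(), None, grm,
                      pen=ph["pen"].to_numpy(), marker_id=qid)
print(f"\nper-company effects (interaction p = {res.p_interaction:.3f}):")
for lev, e in sorted(res.effects.items()):
    print(f"  company {lev}: {e.beta_psd:+.2f} PSD (SE {e.se_psd:.2f})")
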