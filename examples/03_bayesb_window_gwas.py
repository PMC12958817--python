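"""BayesB whole-genome regression with 1 Mb window %EGV and QTL calling,
followed by a conditional scan on the lead SNP.

Run: python examples/03_bayesb_window_gwas.py   (~1 minute)
"""
import numpy as np

from stressqtl.simulate import preset, simulate_cohort
from stressqtl.io import make_windows
from stressqtl.gwas import (
    McmcConfig, call_qtl, conditional_scan, run_bayesb, window_variance,
)

cohort = simulate_cohort(preset("cl_cnur"), seed=1)
ph = cohort.phenotypes
y = np.log(ph["CL_IS"].to_numpy(float))
G = cohort.genotypes
grid = make_windows(G.marker_map, 1_000_000)

cfg = McmcConfig(chain_length=4000, burn_in=500, thin=2, pi=0.99, seed=7)
post = run_bayesb(y, None, G, cfg, pen=ph["pen"].to_numpy())
print(f"PSRF sigma2e = {post.psrf_sigma2e:.3f}, genetic var = {post.psrf_genetic_var:.3f}")

windows = window_variance(post, grid, G)
calls = call_qtl(windows, post)
print(f"\n{len(calls)} windows with %EGV > 1; top 3:")
for c in calls[:3]:
    lead = c.lead_snps[0] if c.lead_snps else ("-", 0.0)
    print(f"  {c.window:10s} %EGV = {c.egv_pct:6.2f}  lead SNP {lead[0]} (PIP {lead[1]:.2f})")

# conditional scan on the top call's lead SNP
lead_id = calls[0].lead_snps[0][0]
lead_idx = G.marker_map.index[G.marker_map["id"] == lead_id][0]
z = G.dosage_float()[:, lead_idx]
cond = conditional_scan(y, None, z, G, cfg, pen=ph["pen"].to_numpy(),
                        exclude_markers=[lead_id])
cond_windows = window_variance(cond, grid, G)
focal = next(w for w in cond_windows if w.window == calls[0].window)
print(f"\nfocal window %EGV after conditioning on {lead_id}: {focal.egv_pct:.2f}")
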