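# stressqtl

Quantitative genetics of hair stress-hormone traits in pigs under infectious
versus noninfectious stress: synthetic cohort simulation, genomic REML
variance components, BayesB window-based GWAS with QTL calling, bivariate
pleiotropy detection, conditional fine mapping, and comparative gene set
enrichment analysis (cGSEA).

## The science

Hair cortisol integrates hypothalamic–pituitary–adrenal activity over weeks,
making it a candidate biomarker for chronic stress load and disease
resilience in livestock. The analyses implemented here follow a study design
in which the same pigs are sampled twice: once after a quarantine nursery
(noninfectious social/environmental stress, "NIS") and once after a natural
polymicrobial disease challenge (infectious stress, "IS").

The package reproduces the statistical machinery of that design on synthetic
cohorts with a known truth:

- **Simulation** (`stressqtl.simulate`): genotypes with first-order Markov
  "copying" LD, a major cortisol QTL embedded in a frequency-matched LD block
  (sample MAF ≈ 9%), an infinitesimal polygenic background, pen/batch/company
  structure, assay noise, and log-normal hormone scales. Presets `cl_cnur`
  (univariate IS cortisol, h² = 0.27, QTL share 37.8% of genetic variance),
  `cl_bivar` (NIS + IS cortisol, total genetic correlation 0.52, shared QTL)
  and `null` (no QTL) encode the study's published estimates.
- **Variance components** (`stressqtl.varcomp`): AI-REML animal models
  (GRM + pen + optional litter random effects), univariate and bivariate with
  partial trait overlap, genetic/phenotypic correlations, and likelihood-ratio
  tests for r_g = 0/±1 and for fixed effects.
- **GWAS** (`stressqtl.gwas`): BayesB MCMC (uni- and bivariate with a shared
  inclusion indicator), 1 Mb window percent of estimated genetic variance
  (%EGV), QTL calls at %EGV > 1 with lead SNPs at PIP > 0.01, the AD
  covariance-sign statistic for pleiotropy on 0.25 Mb windows (flagged at
  AD > 0.02), adjustment of IS cortisol for its NIS baseline, and conditional
  scans that refit the genome with a lead SNP as a fixed covariate.
- **Fine mapping** (`stressqtl.finemap`): GLS allele-substitution effects with
  variance components held at their REML estimates, percent change on the
  hormone scale (100·(1−exp(β))), composite-genotype LD r², and
  company-nested effect estimates with interaction LRTs.
- **Enrichment** (`stressqtl.enrichment`): weighted Kolmogorov–Smirnov GSEA
  with permutation nulls and pooled FDR, plus the paper's comparative GSEA
  that classifies gene sets by where they are significant (IS-only, NIS-only,
  both) into postulates about infectious vs noninfectious stress biology.
- **Pipeline** (`stressqtl.pipeline` and the `stressqtl` CLI): a resumable,
  manifest-tracked seven-stage run (simulate → preprocess → varcomp → gwas →
  pleiotropy → finemap → enrichment) driven by a YAML config.

`docs/methods.md` documents every method and the deliberate modeling
decisions in detail.

## Worked example

Simulate the IS-phase cortisol cohort and estimate heritability
(`examples/01_simulate_and_heritability.py`):

```python
import numpy as np
from stressqtl.simulate import preset, simulate_cohort
from stressqtl.varcomp import compute_grm, design_from_table, fit_univariate

cohort = simulate_cohort(preset("cl_cnur"), seed=1)
ph = cohort.phenotypes
y = np.log(ph["CL_IS"].to_numpy(float))
X, names = design_from_table(ph, factors=["batch"], covariates=["age_entry"])
grm = compute_grm(cohort.genotypes, method="standardized")
fit = fit_univariate(y, X, grm, pen=ph["pen"].to_numpy(), fixed_names=names)
```

Output:

```
cohort: 600 pigs, 5000 markers
QTL marker: snp_2_24600000 (sample MAF 0.083)

h2 = 0.295 (SE 0.103), converged=True
  var[genetic] = 0.2854 (SE 0.1035)
  var[pen] = 0.0477 (SE 0.0250)
  var[residual] = 0.6354 (SE 0.1005)
```

Run the BayesB window GWAS on the same cohort
(`examples/03_bayesb_window_gwas.py`):

```
PSRF sigma2e = 1.002, genetic var = 0.999

8 windows with %EGV > 1; top 3:
  chr2:24    %EGV =  40.31  lead SNP snp_2_24600000 (PIP 1.00)
  chr4:22    %EGV =   4.03  lead SNP snp_4_22225860 (PIP 0.41)
  chr4:7     %EGV =   2.78  lead SNP snp_4_7101170 (PIP 0.44)

focal window %EGV after conditioning on snp_2_24600000: 0.27
```

The simulated QTL window carries ~40% of the genetic variance, its lead SNP
is recovered with PIP 1.00, and conditioning on it removes the signal — the
paper's hallmark result on its own major cortisol QTL.

Fine mapping (`examples/04_finemap_effects.py`):

```
snp_2_24600000: beta = -0.788 +/- 0.105 (log scale), -0.79 PSD, p = 5.37e-14, MAF = 0.083
per-copy change on the hormone scale: 54.5% reduction
```

The bivariate analysis (`examples/02_bivariate_genetic_correlation.py`)
estimates r_g = 0.519 (SE 0.222) between NIS and IS cortisol and shows the
drop after conditioning on the QTL dosage; the full pipeline with report
tables is `examples/05_full_pipeline.py`, or from the shell:

```sh
stressqtl pipeline run --config run.yaml
stressqtl pipeline report <run-dir>
```

## Reproduction

Everything is deterministic given seeds; there are no bundled data files.

Run the test suite (≈ 20 min on one CPU; includes the acceptance criteria):

```sh
pytest -o addopts= -p no:cacheprovider -q
```

Recompute the acceptance-target statistics from scratch (≈ 6 min):

```sh
python scripts/acceptance.py --seed 1 --out acceptance.json
```

With seed 1 this reproduces: t2 = 0.273 (target 0.27 ± 0.05), t3 = 0.551
(0.52 ± 0.08), t4 = 0.196 (0.13 ± 0.10), t5 = 32.7 (37.8 ± 6), t6 = 45.0
(45.3 ± 6), t7 = 1.0 (exact), t8 = 8.7% (9 ± 1). Cohort seeds are pinned by
the target definitions; `--seed` controls only the MCMC chain seeds.

**Known-red tests.** Two clauses of the acceptance criteria are asserted as
specified and deliberately left failing, because the published null
calibration does not transfer to the desk-scale genome (250 one-megabase
windows instead of 2,446): the %EGV statistic is self-normalized, so chance
windows clear the 1%-of-EGV call threshold under the null preset, and about
13% of null 0.25 Mb windows exceed AD = 0.02 under the bivariate sampler's
shared-indicator prior. These are
`test_criterion_5_pleiotropy` (its null-AD clause) and
`test_criterion_7e_sampler_null_calibration` in `tests/test_acceptance.py`;
the measured analysis is in the docstrings and in `docs/methods.md` (known
limitations).
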