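"""Synthetic genotype-phenotype cohorts for hair stress-hormone genetics.

The generator reproduces the statistical architecture the downstream
analyses assume: biallelic SNPs with first-order-Markov linkage
disequilibrium along each chromosome, a shared major QTL of configurable
minor-allele frequency and variance share, a correlated polygenic
background, batch/pen/litter/company design factors, age and storage-day
covariates, log-normal hormone scales, and assay replicates with a
configurable measurement CV.

Phenotypes are simulated on the natural-log scale with unit phenotypic
variance (before fixed effects), then exponentiated; analyses re-log them,
so one "phenotypic standard deviation" of the log trait equals 1 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from .io import MISSING, GenotypeMatrix


@dataclass
class QtlSpec:
    """A shared biallelic QTL.

    The implied allele-substitution effect for trait t is
    ``beta_t = -sqrt(share_t * sigma2_g_t / (2 p (1 - p)))`` — the minor
    allele lowers the hormone level, with the sign shared across traits.
    """

    chromosome: int = 1          # 0-based index into the simulated chromosomes
    position: int = 24_600_000   # bp
    maf: float = 0.09
    var_share_per_trait: tuple[float, ...] = (0.378,)


@dataclass
class TraitSimSpec:
    """Variance architecture and design-effect sizes for one hormone trait."""

    name: str
    h2: float
    pen_frac: float = 0.0
    litter_frac: float = 0.0
    batch_sd: float = 0.3        # SD of batch effects on the log scale
    storage_slope: float = 0.002  # per day of storage, log scale
    age_slope: float = 0.005      # per day of age at entry, log scale
    mean: float = 2.2             # log pg/mg (~9 pg/mg)
    n_replicates: int = 2         # 2 -> duplicate rule, 3 -> best-pair-of-three
    missing_rate: float = 0.0     # completely-at-random trait missingness
    scale: str = "log-normal"

    def residual_frac(self) -> float:
        return 1.0 - self.h2 - self.pen_frac - self.litter_frac


@dataclass
class SimConfig:
    n_individuals: int = 600
    n_chromosomes: int = 5
    chrom_length: int = 50_000_000
    n_markers: int = 5_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.7
    qtl: QtlSpec | None = None
    traits: list[TraitSimSpec] = field(default_factory=list)
    rg_polygenic: float = 0.0
    n_background_loci: int | None = None  # None -> infinitesimal (every marker causal)
    batch_count: int = 6
    pen_count: int = 40
    litter_count: int = 120
    company_count: int = 7
    assay_cv: float = 0.07
    age_range: tuple[int, int] = (40, 60)      # days at entry
    storage_range: tuple[int, int] = (0, 120)  # days of ground-sample storage

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5) or (lo == hi == 0):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if self.n_markers % self.n_chromosomes != 0:
            raise ValueError("n_markers must be divisible by n_chromosomes")
        if not -1.0 <= self.rg_polygenic <= 1.0:
            raise ValueError(f"rg_polygenic {self.rg_polygenic} outside [-1, 1]")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        if not self.traits:
            raise ValueError("at least one trait is required")
        for t in self.traits:
            fracs = (t.h2, t.pen_frac, t.litter_frac)
            if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
                raise ValueError(
                    f"trait {t.name}: variance fractions must be nonnegative "
                    "and sum to <= 1"
                )
        if self.qtl is not None:
            q = self.qtl
            if not 0 < q.maf <= 0.5:
                raise ValueError("QTL maf must lie in (0, 0.5]")
            if len(q.var_share_per_trait) != len(self.traits):
                raise ValueError("QTL var_share_per_trait must match trait count")
            if any(not 0 <= s <= 1 for s in q.var_share_per_trait):
                raise ValueError("QTL variance shares must lie in [0, 1]")
            if not 0 <= q.chromosome < self.n_chromosomes:
                raise ValueError("QTL chromosome index out of range")


@dataclass
class CohortTruth:
    """Simulated ground truth kept alongside a cohort for validation."""

    qtl_marker: str | None
    qtl_index: int | None
    qtl_beta: np.ndarray | None           # per trait, log scale
    genetic_values: np.ndarray            # n x traits, total (QTL + polygenic)
    polygenic_values: np.ndarray          # n x traits
    latent: np.ndarray                    # n x traits, log scale incl. noise


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: CohortTruth
    config: SimConfig

    def __iter__(self):
        return iter((self.genotypes, self.phenotypes))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig, seed: int) -> GenotypeMatrix:
    """Simulate SNP dosages with first-order Markov copying LD.

    Each haplotype walks along the chromosome: at every marker the allele
    is copied from the previous marker with probability ``ld_decay`` and
    otherwise drawn fresh from that marker's base frequency.  Copying makes
    adjacent-marker correlation decay geometrically with distance in
    markers, couples allele frequencies locally (so a low-MAF locus gets
    high-r2 neighbours, as in dense real panels), and ``ld_decay = 0``
    gives independent markers.  If a QTL is configured, the marker nearest
    its position is moved exactly onto it, given the QTL's allele
    frequency, and always drawn fresh so its sample MAF is binomial around
    the specification.
    """
    config.validate()
    rng = np.random.default_rng([int(seed), 0xA11E1E])
    n = config.n_individuals
    m_per = config.n_markers // config.n_chromosomes
    rho = config.ld_decay

    all_dos, rows = [], []
    for c in range(config.n_chromosomes):
        pos = np.sort(
            rng.choice(config.chrom_length, size=m_per, replace=False)
        ).astype(np.int64)
        freqs = rng.uniform(*config.maf_range, size=m_per)
        qtl_j = None
        if config.qtl is not None and c == config.qtl.chromosome:
            j = int(np.argmin(np.abs(pos - config.qtl.position)))
            pos[j] = config.qtl.position
            pos = np.sort(pos)
            qtl_j = int(np.searchsorted(pos, config.qtl.position))
            # frequency-matched local block: high-r2 neighbours as in the
            # dense real panels where lead SNPs have r2 ~ 0.9 partners
            lo_b = max(qtl_j - 2, 0)
            hi_b = min(qtl_j + 3, m_per)
            freqs[lo_b:hi_b] = config.qtl.maf

        # Markov copying along 2n haplotypes
        fresh = (rng.random((2 * n, m_per)) < freqs[None, :]).astype(np.int8)
        copy = rng.random((2 * n, m_per)) < rho
        copy[:, 0] = False
        if qtl_j is not None:
            # no copying into the block: its emergent frequency stays at the
            # QTL MAF while the QTL keeps frequency-matched high-r2 partners
            copy[:, lo_b] = False
        haps = np.empty((2 * n, m_per), dtype=np.int8)
        haps[:, 0] = fresh[:, 0]
        for j in range(1, m_per):
            haps[:, j] = np.where(copy[:, j], haps[:, j - 1], fresh[:, j])
        dos = haps[:n] + haps[n:]
        all_dos.append(dos)
        for j in range(m_per):
            rows.append(
                {
                    "chrom": f"chr{c + 1}",
                    "pos": int(pos[j]),
                    "id": f"snp_{c + 1}_{int(pos[j])}",
                    "a1": "A",
                    "a2": "G",
                }
            )
    return GenotypeMatrix(
        np.concatenate(all_dos, axis=1), pd.DataFrame(rows)
    )


def qtl_marker_index(G: GenotypeMatrix, config: SimConfig) -> int:
    """Index of the marker placed on the configured QTL position."""
    if config.qtl is None:
        raise ValueError("config has no QTL")
    chrom = f"chr{config.qtl.chromosome + 1}"
    mask = (G.marker_map["chrom"] == chrom) & (
        G.marker_map["pos"] == config.qtl.position
    )
    idx = np.flatnonzero(mask.to_numpy())
    if idx.size != 1:
        raise ValueError("QTL marker not found in genotype matrix")
    return int(idx[0])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _scale_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a centered vector so its sample variance is exactly target_var."""
    x = x - x.mean()
    v = x.var(ddof=1)
    if target_var <= 0 or v <= 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_cohort(config: SimConfig, seed: int) -> Cohort:
    """Simulate genotypes plus phenotypes for every configured trait.

    The latent log-scale value per trait is
    ``mu + batch + age*slope + storage*slope + dosage*beta + polygenic
    + pen + litter + residual``; the reported hormone value is its
    exponential, observed through ``n_replicates`` assay replicates with
    log-normal noise of coefficient of variation ``assay_cv``.

    Polygenic values of the two traits are drawn with correlation
    ``rg_polygenic`` and rescaled to hit each trait's background variance
    exactly; the QTL effect uses its nominal allele frequency, so its
    realized variance share floats within binomial sampling error.
    """
    config.validate()
    G = simulate_genotypes(config, seed)
    rng = np.random.default_rng([int(seed), 0x9E907])
    n = config.n_individuals
    n_traits = len(config.traits)

    # design factors
    batch = rng.integers(config.batch_count, size=n)
    pen = rng.integers(config.pen_count, size=n)
    litter = rng.integers(config.litter_count, size=n)
    company = rng.integers(config.company_count, size=n)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    storage = rng.integers(config.storage_range[0], config.storage_range[1] + 1, size=n)

    # QTL
    qtl_idx = qtl_beta = qtl_id = None
    g_qtl = np.zeros((n, n_traits))
    if config.qtl is not None:
        qtl_idx = qtl_marker_index(G, config)
        qtl_id = str(G.marker_map["id"].iloc[qtl_idx])
        p = config.qtl.maf
        qtl_beta = np.array(
            [
                -np.sqrt(s * t.h2 / (2.0 * p * (1.0 - p)))
                for s, t in zip(config.qtl.var_share_per_trait, config.traits)
            ]
        )
        dq = G.dosages[:, qtl_idx].astype(float)
        g_qtl = (dq - dq.mean())[:, None] * qtl_beta[None, :]

    # polygenic background from marker effects with cross-trait correlation
    m = G.n_markers
    if config.n_background_loci is None:
        bg = np.arange(m)
    else:
        candidates = np.setdiff1d(np.arange(m), [] if qtl_idx is None else [qtl_idx])
        bg = rng.choice(candidates, size=min(config.n_background_loci, candidates.size), replace=False)
    corr = np.full((n_traits, n_traits), config.rg_polygenic)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_traits))
    if config.n_background_loci is None:
        # infinitesimal: equal variance contribution per marker
        Zbg = G.dosage_float()[:, bg]
        pbg = Zbg.mean(axis=0) / 2.0
        w = 1.0 / np.sqrt(np.maximum(2 * pbg * (1 - pbg), 1e-8))
        u = rng.standard_normal((bg.size, n_traits)) @ chol.T
        u *= w[:, None]
    else:
        Zbg = G.dosage_float()[:, bg]
        u = rng.standard_normal((bg.size, n_traits)) @ chol.T
    Zbg = Zbg - Zbg.mean(axis=0)
    g_poly_raw = Zbg @ u
    g_poly = np.empty_like(g_poly_raw)
    for t, spec in enumerate(config.traits):
        share = (
            config.qtl.var_share_per_trait[t] if config.qtl is not None else 0.0
        )
        g_poly[:, t] = _scale_to_variance(g_poly_raw[:, t], (1.0 - share) * spec.h2)

    # random design effects and residuals
    latent = np.empty((n, n_traits))
    pheno = pd.DataFrame(
        {
            "id": [f"ind{i:05d}" for i in range(n)],
            "batch": batch,
            "pen": pen,
            "litter": litter,
            "company": company,
            "age_entry": age,
            "storage_days": storage,
        }
    )
    for t, spec in enumerate(config.traits):
        batch_eff = rng.normal(0.0, spec.batch_sd, size=config.batch_count)[batch]
        pen_eff = (
            rng.normal(0.0, np.sqrt(spec.pen_frac), size=config.pen_count)[pen]
            if spec.pen_frac > 0
            else np.zeros(n)
        )
        litter_eff = (
            rng.normal(0.0, np.sqrt(spec.litter_frac), size=config.litter_count)[litter]
            if spec.litter_frac > 0
            else np.zeros(n)
        )
        resid = rng.normal(0.0, np.sqrt(spec.residual_frac()), size=n)
        latent[:, t] = (
            spec.mean
            + batch_eff
            + spec.age_slope * (age - age.mean())
            + spec.storage_slope * (storage - storage.mean())
            + g_qtl[:, t]
            + g_poly[:, t]
            + pen_eff
            + litter_eff
            + resid
        )
        true_value = np.exp(latent[:, t])
        sigma_m = np.sqrt(np.log1p(config.assay_cv**2))
        reps = true_value[:, None] * np.exp(
            rng.normal(0.0, sigma_m, size=(n, spec.n_replicates)) - sigma_m**2 / 2.0
        )
        from .io import aggregate_replicates

        mode = "duplicate" if spec.n_replicates == 2 else "best_pair_of_three"
        if spec.n_replicates in (2, 3):
            agg = np.array([aggregate_replicates(r, mode)[0] for r in reps])
        else:
            agg = reps.mean(axis=1)
        if spec.missing_rate > 0:
            mask = rng.random(n) < spec.missing_rate
            agg = np.where(mask, np.nan, agg)
        for k in range(spec.n_replicates):
            pheno[f"{spec.name}_rep{k + 1}"] = reps[:, k]
        pheno[spec.name] = agg

    truth = CohortTruth(
        qtl_marker=qtl_id,
        qtl_index=qtl_idx,
        qtl_beta=qtl_beta,
        genetic_values=g_qtl + g_poly,
        polygenic_values=g_poly,
        latent=latent,
    )
    return Cohort(G, pheno, truth, config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# total r_g target 0.52 = sqrt(.453*.378) + rg_poly*sqrt(.547*.622)
RG_POLY_CL_BIVAR = (0.52 - np.sqrt(0.453 * 0.378)) / np.sqrt(
    (1 - 0.453) * (1 - 0.378)
)


def preset(name: str) -> SimConfig:
    """Named study-condition presets.

    ``cl_cnur``: one cortisol-under-infectious-stress trait, h2 0.27 with a
    MAF-0.09 QTL explaining 37.8% of genetic variance.  ``cl_bivar``: the
    cortisol trait under noninfectious (h2 0.33, QTL share 0.453) and
    infectious (h2 0.27, share 0.378) stress with a shared QTL and total
    genetic correlation 0.52.  ``null``: two polygenic traits (h2 0.25,
    fully infinitesimal background, no QTL, zero polygenic correlation).
    """
    if name == "cl_cnur":
        return SimConfig(
            qtl=QtlSpec(var_share_per_trait=(0.378,)),
            traits=[TraitSimSpec(name="CL_IS", h2=0.27, pen_frac=0.05)],
        )
    if name == "cl_bivar":
        return SimConfig(
            qtl=QtlSpec(var_share_per_trait=(0.453, 0.378)),
            traits=[
                TraitSimSpec(name="CL_NIS", h2=0.33, pen_frac=0.05),
                TraitSimSpec(name="CL_IS", h2=0.27, pen_frac=0.05),
            ],
            rg_polygenic=float(RG_POLY_CL_BIVAR),
        )
    if name == "null":
        return SimConfig(
            qtl=None,
            traits=[
                TraitSimSpec(name="T1_NIS", h2=0.25, pen_frac=0.05),
                TraitSimSpec(name="T2_IS", h2=0.25, pen_frac=0.05),
            ],
            rg_polygenic=0.0,
            n_background_loci=None,
        )
    raise KeyError(f"unknown preset {name!r}")


def scaled_preset(name: str, n_individuals: int | None = None, n_markers: int | None = None) -> SimConfig:
    """A preset with cohort or panel size overridden (for small test runs)."""
    cfg = preset(name)
    changes = {}
    if n_individuals is not None:
        changes["n_individuals"] = n_individuals
    if n_markers is not None:
        changes["n_markers"] = n_markers
    return replace(cfg, **changes)


# ---------------------------------------------------------------------------
# synthetic annotation helpers (for enrichment tests and examples)
# ---------------------------------------------------------------------------

def simulate_gene_annotation(config: SimConfig, n_genes: int, seed: int) -> pd.DataFrame:
    """Random non-pathological gene intervals (synthetic stand-in annotation)."""
    rng = np.random.default_rng([int(seed), 0x6E4E5])
    chroms = rng.integers(config.n_chromosomes, size=n_genes)
    starts = rng.integers(0, config.chrom_length - 100_000, size=n_genes)
    lengths = rng.integers(2_000, 100_000, size=n_genes)
    return pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chroms],
            "start": starts,
            "end": starts + lengths,
            "gene": [f"gene{i:05d}" for i in range(n_genes)],
        }
    )


def simulate_gene_sets(
    genes: pd.DataFrame, n_sets: int, size_range: tuple[int, int], seed: int
) -> dict[str, list[str]]:
    """Random gene sets over a synthetic annotation (GMT-shaped dict)."""
    rng = np.random.default_rng([int(seed), 0x6337])
    names = genes["gene"].to_numpy()
    library = {}
    for s in range(n_sets):
        k = int(rng.integers(size_range[0], size_range[1] + 1))
        library[f"set{s:04d}"] = list(rng.choice(names, size=k, replace=False))
    return library
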