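"""Genotype/phenotype I/O and phenotype preprocessing.

Containers and format support for the pipeline: dosage matrices with a
physical marker map (PLINK bed/bim/fam and VCF), non-overlapping window
grids, GMT gene-set libraries, BED gene annotations, and the assay-level
phenotype quality-control rules (replicate aggregation with a CV filter,
upper-threshold outlier removal, log transforms).

All coordinates are 0-based, half-open internally.  PLINK .bim and VCF
positions (1-based) are converted on read and restored on write.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: sentinel for a missing dosage call
MISSING = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix plus a physical marker map.

    ``dosages`` holds minor/alt-allele counts in {0, 1, 2} as int8 with
    :data:`MISSING` (-1) for no-calls.  ``marker_map`` is a DataFrame with
    columns ``chrom`` (str), ``pos`` (0-based bp, int), ``id``, ``a1``,
    ``a2``; positions are strictly increasing within each chromosome.
    """

    dosages: np.ndarray
    marker_map: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        n, m = self.dosages.shape
        if len(self.marker_map) != m:
            raise ValueError(
                f"marker map has {len(self.marker_map)} rows for {m} markers"
            )
        if not self.sample_ids:
            self.sample_ids = [f"ind{i:05d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if self.marker_map["id"].duplicated().any():
            raise ValueError("duplicate marker ids in marker map")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions not strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker allele frequency of the counted allele (missing skipped)."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return np.nanmean(d, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def dosage_float(self, impute_mean: bool = True) -> np.ndarray:
        """Float64 dosage matrix; missing calls imputed to the marker mean."""
        d = self.dosages.astype(np.float64)
        miss = self.dosages == MISSING
        if miss.any():
            d[miss] = np.nan
            if impute_mean:
                col_mean = np.nanmean(d, axis=0)
                idx = np.where(miss)
                d[idx] = col_mean[idx[1]]
        return d

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.marker_map["id"] == marker_id).to_numpy())
        if hits.size != 1:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(hits[0])


@dataclass
class WindowGrid:
    """Non-overlapping, tiled, half-open [start, end) windows per chromosome."""

    size_bp: int
    windows: pd.DataFrame  # columns: chrom, start, end, window

    def window_of(self, chrom: str, pos: int) -> str:
        return f"{chrom}:{pos // self.size_bp}"

    def assign_markers(self, marker_map: pd.DataFrame) -> pd.Series:
        """Window id for every marker (indexed like ``marker_map``)."""
        return pd.Series(
            [
                self.window_of(c, p)
                for c, p in zip(marker_map["chrom"], marker_map["pos"])
            ],
            index=marker_map.index,
            name="window",
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> dosage of allele 1 ("minor"): 00=2, 01=missing, 10=1, 11=0
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam (SNP-major bed, counted allele = a1)."""
    prefix = Path(prefix)
    n, m = G.dosages.shape
    mm = G.marker_map
    bim = pd.DataFrame(
        {
            "chrom": mm["chrom"],
            "id": mm["id"],
            "cm": 0,
            "pos": mm["pos"] + 1,  # bim is 1-based
            "a1": mm.get("a1", pd.Series(["A"] * m)),
            "a2": mm.get("a2", pd.Series(["G"] * m)),
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.sample_ids,
            "iid": G.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        codes[(G.dosages.T == dosage)] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = codes[:, k::4]
        packed[:, : cols.shape[1]] |= cols << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read .bed/.bim/.fam written in SNP-major order."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if body.size != m * n_bytes:
        raise ValueError(
            f"bed payload has {body.size} bytes, expected {m * n_bytes} "
            f"for {n} individuals x {m} markers"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n), dtype=np.uint8)
    for k in range(4):
        chunk = (body >> (2 * k)) & 0b11
        cols = codes[:, k::4]
        cols[:] = chunk[:, : cols.shape[1]]
    dosages = _BED_DECODE[codes].T.copy()
    marker_map = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int) - 1,
            "id": bim["id"],
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    return GenotypeMatrix(dosages, marker_map, [str(s) for s in fam[1]])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write unphased diploid GTs; the counted allele is written as ALT."""
    path = Path(path)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in G.marker_map["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        mm = G.marker_map
        for j in range(G.n_markers):
            row = mm.iloc[j]
            calls = "\t".join(gt_str[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t{row['id']}\t"
                f"{row.get('a2', 'G')}\t{row.get('a1', 'A')}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into dosages of the ALT allele (missing kept as MISSING)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosages, rows = [], []
    for var in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        gt = np.asarray(var.gt_types)
        d = np.where(gt == 3, MISSING, np.where(gt == 2, 2, gt)).astype(np.int8)
        dosages.append(d)
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS) - 1,
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "a1": var.ALT[0] if var.ALT else "A",
                "a2": var.REF,
            }
        )
    return GenotypeMatrix(np.array(dosages).T, pd.DataFrame(rows), samples)


def read_genotypes(path: str | Path, format: str = "plink") -> GenotypeMatrix:
    """Dispatch to :func:`read_plink` (``path`` is a prefix) or :func:`read_vcf`."""
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# gene sets and gene annotations
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, min_size: int = 1, max_size: int | None = None) -> dict[str, list[str]]:
    """Read a GMT gene-set library (name <tab> description <tab> genes...)."""
    library: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            genes = [g for g in parts[2:] if g]
            if len(genes) >= min_size and (max_size is None or len(genes) <= max_size):
                library[parts[0]] = genes
    if not library:
        raise ValueError(f"no gene sets retained from {path}")
    return library


def write_gmt(library: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in library.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """Read a BED file of gene intervals into (chrom, start, end, gene)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str},
    )
    return df


# ---------------------------------------------------------------------------
# phenotype preprocessing
# ---------------------------------------------------------------------------

def aggregate_replicates(
    replicates, mode: str = "duplicate", cv_threshold: float = 0.20
):
    """Combine assay replicates into one value with a CV quality flag.

    ``duplicate``: mean and CV of the two replicates.  ``best_pair_of_three``:
    of the three possible pairs, take the pair with the lowest CV.  CV is the
    sample standard deviation (n-1) over the mean of the replicates used.
    The flag is True iff the final CV strictly exceeds ``cv_threshold``,
    marking an assay that would be sent for reanalysis.
    """
    reps = np.asarray(replicates, dtype=float)
    if np.any(reps <= 0):
        raise ValueError(f"nonpositive replicate value in {replicates!r}")

    def pair_stats(pair):
        mean = pair.mean()
        cv = pair.std(ddof=1) / mean
        return mean, cv

    if mode == "duplicate":
        if reps.size != 2:
            raise ValueError("duplicate mode expects exactly 2 replicates")
        value, cv = pair_stats(reps)
    elif mode == "best_pair_of_three":
        if reps.size != 3:
            raise ValueError("best_pair_of_three mode expects exactly 3 replicates")
        value, cv = min(
            (pair_stats(np.array(p)) for p in itertools.combinations(reps, 2)),
            key=lambda t: t[1],
        )
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return float(value), float(cv), bool(cv > cv_threshold)


def reanalyze_replicates(original, reanalyzed, mode="duplicate", cv_threshold=0.20):
    """Apply the reanalysis rule: keep the new assay only if its CV is lower."""
    v0, cv0, f0 = aggregate_replicates(original, mode, cv_threshold)
    v1, cv1, f1 = aggregate_replicates(reanalyzed, mode, cv_threshold)
    return (v1, cv1, f1) if cv1 < cv0 else (v0, cv0, f0)


def filter_outliers(values: pd.Series, upper_threshold: float):
    """Remove values strictly greater than the threshold; log the removals.

    Returns ``(retained, removal_log)`` where the log is a DataFrame with the
    ids (index) and values removed.
    """
    if upper_threshold <= 0:
        raise ValueError("upper_threshold must be positive")
    values = pd.Series(values)
    removed = values[values > upper_threshold]
    retained = values[~(values > upper_threshold)]
    log = pd.DataFrame({"id": removed.index, "value": removed.to_numpy()})
    return retained, log


def transform_trait(values, kind: str = "ln") -> np.ndarray:
    """Natural-log transforms used for hormone levels (ln) and counts (ln1p)."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if kind == "ln":
        bad = np.flatnonzero(finite & (arr <= 0))
        if bad.size:
            raise ValueError(f"ln transform requires positive values; record {bad[0]} is {arr[bad[0]]}")
        return np.log(arr)
    if kind == "ln1p":
        bad = np.flatnonzero(finite & (arr < 0))
        if bad.size:
            raise ValueError(f"ln1p transform requires nonnegative values; record {bad[0]} is {arr[bad[0]]}")
        return np.log1p(arr)
    raise ValueError(f"unknown transform {kind!r}")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(marker_map: pd.DataFrame, size_bp: int, chrom_length: int | None = None) -> WindowGrid:
    """Tile each chromosome with non-overlapping half-open windows.

    Windows run from 0 to ``chrom_length`` (or to the last marker's window
    when no length is given), so every marker maps to exactly one window.
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    rows = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        last = chrom_length if chrom_length is not None else int(grp["pos"].max()) + 1
        n_win = int(np.ceil(last / size_bp))
        for w in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * size_bp,
                    "end": (w + 1) * size_bp,
                    "window": f"{chrom}:{w}",
                }
            )
    return WindowGrid(size_bp, pd.DataFrame(rows))


def map_genes_to_windows(genes: pd.DataFrame, grid: WindowGrid) -> dict[str, str]:
    """Assign each gene to the window containing its interval midpoint.

    Genes on chromosomes absent from the grid are skipped (with a warning in
    the returned mapping simply omitted).
    """
    known = set(grid.windows["chrom"].unique())
    mapping: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        if str(row.chrom) not in known:
            continue
        mid = (int(row.start) + int(row.end)) // 2
        mapping[str(row.gene)] = grid.window_of(str(row.chrom), mid)
    return mapping
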