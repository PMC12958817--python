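"""Window-ranked GSEA and the comparative GSEA (cGSEA) postulate classifier.

Genes inherit the statistic of the 0.25 Mb window containing their midpoint
(:func:`stressqtl.io.map_genes_to_windows`).  :func:`gsea` implements the
weighted Kolmogorov-Smirnov enrichment score with a gene-permutation null,
NES normalization by the same-sign null mean, and the positive/negative-pool
FDR of the GSEA software.  :func:`cgsea` combines three analyses — the
difference ranking (v_IS - v_NIS) and the two single-condition rankings —
into the postulate categories of the study design:

* WPD — "window plastic in disease": enriched among windows whose %EGV is
  larger under infectious stress (positive difference tail).
* WND — enriched in the negative tail (larger under noninfectious stress).
* Sub-categories record where the set is also enriched in the
  single-condition analyses (both, IS only, NIS only, neither).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import WindowVariance

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "PostulateClass",
    "build_ranked_list",
    "enrichment_score",
    "gsea",
    "cgsea",
    "results_to_frame",
]


@dataclass
class RankedList:
    """Gene -> score, held in descending score order (ties: gene-id order)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene ids in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        order = sorted(
            range(len(self.genes)), key=lambda i: (-self.scores[i], self.genes[i])
        )
        self.genes = [self.genes[i] for i in order]
        self.scores = np.asarray([self.scores[i] for i in order], dtype=float)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    signed_q: float            # sign of ES attached to q
    tail: str                  # "WPD"/"WND" for difference lists, "top"/"bottom" otherwise
    n_genes: int


@dataclass
class PostulateClass:
    set_name: str
    category: str


# ---------------------------------------------------------------------------
# ranked lists
# ---------------------------------------------------------------------------

def build_ranked_list(
    windows: list[WindowVariance] | tuple[list[WindowVariance], list[WindowVariance]],
    gene_windows: pd.Series,
    mode: str = "single",
    exclude_qtl: bool = False,
    qtl_threshold: float = 1.0,
) -> RankedList:
    """Gene scores from per-window %EGV statistics.

    ``gene_windows`` maps gene id -> window id (midpoint assignment).  In
    ``single`` mode each gene scores its window's %EGV; in ``difference``
    mode pass a pair of window lists on the same grid and each gene scores
    v_IS - v_NIS.  With ``exclude_qtl``, genes in windows whose %EGV exceeds
    the QTL threshold in any contributing analysis are dropped.
    """
    if mode == "single":
        if isinstance(windows, tuple):
            raise ValueError("single mode takes one window list")
        per = {w.window: w.egv_pct for w in windows}
        excl = {w.window for w in windows if w.egv_pct > qtl_threshold}
        score = per
    elif mode == "difference":
        if not isinstance(windows, tuple) or len(windows) != 2:
            raise ValueError("difference mode takes (windows_IS, windows_NIS)")
        w_is, w_nis = windows
        a = {w.window: w.egv_pct for w in w_is}
        b = {w.window: w.egv_pct for w in w_nis}
        if set(a) != set(b):
            raise ValueError("the two analyses use different window grids")
        score = {w: a[w] - b[w] for w in a}
        excl = {w for w in a if a[w] > qtl_threshold or b[w] > qtl_threshold}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    genes, scores = [], []
    for gene, win in gene_windows.items():
        if win not in score:
            continue
        if exclude_qtl and win in excl:
            continue
        genes.append(str(gene))
        scores.append(score[win])
    if not genes:
        raise ValueError("no gene maps to a scored window")
    return RankedList(genes=genes, scores=np.asarray(scores, dtype=float))


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_walk(scores: np.ndarray, hit: np.ndarray, p: float):
    """Running-sum walk; returns (ES, profile)."""
    n = scores.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    w = np.abs(scores) ** p
    w = np.where(hit, w, 0.0)
    tot = w.sum()
    if tot <= 0:
        # all hit scores are zero: equal hit increments
        w = hit.astype(float)
        tot = w.sum()
    inc = w / tot
    n_miss = n - n_hit
    if n_miss == 0:
        profile = np.cumsum(inc)
        return float(profile.max()), profile
    dec = (~hit).astype(float) / n_miss
    profile = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i]), profile


def enrichment_score(
    ranked: RankedList, gene_set, p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and its running-sum profile."""
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.genes), bool, len(ranked))
    return _es_walk(ranked.scores, hit, p)


# ---------------------------------------------------------------------------
# GSEA with gene-permutation null
# ---------------------------------------------------------------------------

def _nes_and_p(es: float, null: np.ndarray):
    same = null[null >= 0] if es >= 0 else -null[null < 0]
    if same.size == 0 or same.mean() == 0:
        return float("nan"), 1.0
    nes = es / same.mean() if es >= 0 else -(-es) / same.mean()
    p = float((np.sum(same >= abs(es)) + 1) / (same.size + 1))
    return float(nes), p


def gsea(
    ranked: RankedList,
    library: dict[str, list[str]],
    n_perm: int = 500,
    seed: int = 0,
    set_size_bounds: tuple[int, int] = (5, 500),
    weight_p: float = 1.0,
    difference_mode: bool = False,
) -> list[EnrichmentResult]:
    """Gene-set enrichment with gene-label permutation null and pooled FDR.

    Deterministic given ``seed``.  ``difference_mode`` only changes the tail
    labels (WPD/WND instead of top/bottom).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    lo, hi = set_size_bounds
    genes_in_list = set(ranked.genes)
    sizes: dict[str, int] = {}
    hits: dict[str, np.ndarray] = {}
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    for name, members in library.items():
        idx = sorted({gene_pos[g] for g in members if g in genes_in_list})
        if lo <= len(idx) <= hi:
            sizes[name] = len(idx)
            h = np.zeros(len(ranked), dtype=bool)
            h[idx] = True
            hits[name] = h
    if not hits:
        raise ValueError("library empty after size filtering")

    rng = np.random.default_rng(seed)
    scores = ranked.scores
    n = len(ranked)

    results: list[tuple[str, float, float, float, np.ndarray]] = []
    # one permutation stream per set size so equally sized sets share nulls
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes.values())):
        null = np.empty(n_perm)
        for t in range(n_perm):
            perm_idx = rng.choice(n, size=k, replace=False)
            h = np.zeros(n, dtype=bool)
            h[perm_idx] = True
            null[t], _ = _es_walk(scores, h, weight_p)
        null_by_size[k] = null

    rows = []
    for name, h in hits.items():
        es, _ = _es_walk(scores, h, weight_p)
        null = null_by_size[sizes[name]]
        nes, p = _nes_and_p(es, null)
        null_same = null[null >= 0] if es >= 0 else null[null < 0]
        null_mean = (
            np.abs(null_same).mean() if null_same.size else float("nan")
        )
        # NES values of the null, normalized the same way, for the FDR pools
        null_nes = (
            null_same / null_mean if null_same.size and null_mean > 0 else np.empty(0)
        )
        rows.append((name, es, nes, p, sizes[name], null_nes))

    # positive/negative-pool FDR (GSEA software procedure)
    obs_nes = np.array([r[2] for r in rows])
    null_pos = np.concatenate(
        [r[5] for r in rows if r[1] >= 0] or [np.empty(0)]
    )
    null_neg = np.concatenate(
        [np.abs(r[5]) for r in rows if r[1] < 0] or [np.empty(0)]
    )
    obs_pos = obs_nes[obs_nes >= 0]
    obs_neg = -obs_nes[obs_nes < 0]

    out: list[EnrichmentResult] = []
    for name, es, nes, p, k, _ in rows:
        if not np.isfinite(nes):
            q = 1.0
        elif es >= 0:
            num = np.mean(null_pos >= nes) if null_pos.size else 1.0
            den = np.mean(obs_pos >= nes) if obs_pos.size else 1.0
            q = min(num / max(den, 1e-12), 1.0)
        else:
            num = np.mean(null_neg >= -nes) if null_neg.size else 1.0
            den = np.mean(obs_neg >= -nes) if obs_neg.size else 1.0
            q = min(num / max(den, 1e-12), 1.0)
        if difference_mode:
            tail = "WPD" if es >= 0 else "WND"
        else:
            tail = "top" if es >= 0 else "bottom"
        out.append(
            EnrichmentResult(
                set_name=name,
                es=float(es),
                nes=float(nes),
                p_value=float(p),
                fdr_q=float(q),
                signed_q=float(q if es >= 0 else -q),
                tail=tail,
                n_genes=k,
            )
        )

    # enforce monotone q within each sign pool (more extreme NES never has
    # a larger q)
    for sign in (1, -1):
        grp = [r for r in out if (r.es >= 0) == (sign == 1)]
        grp.sort(key=lambda r: -abs(r.nes) if np.isfinite(r.nes) else 0.0)
        # step-up: a more extreme NES never carries a larger q than a less
        # extreme one in the same pool
        cummin = 1.0
        for r in reversed(grp):
            cummin = min(cummin, r.fdr_q)
            r.fdr_q = cummin
            r.signed_q = cummin if r.es >= 0 else -cummin
    out.sort(key=lambda r: r.p_value)
    return out


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "signed_q": [r.signed_q for r in results],
            "tail": [r.tail for r in results],
            "n_genes": [r.n_genes for r in results],
        }
    )


# ---------------------------------------------------------------------------
# cGSEA postulate classification
# ---------------------------------------------------------------------------

def cgsea(
    results_diff: list[EnrichmentResult],
    results_is: list[EnrichmentResult],
    results_nis: list[EnrichmentResult],
    fdr: float = 0.25,
) -> list[PostulateClass]:
    """Assign each gene set to one postulate category.

    Significance is FDR q <= ``fdr`` in each analysis.  Sets significant in
    the difference analysis get WPD (positive ES) or WND (negative ES) with
    a sub-category for single-condition status; the rest get a
    not-significant category recording any single-condition enrichment.
    """
    names_d = {r.set_name for r in results_diff}
    names_i = {r.set_name for r in results_is}
    names_n = {r.set_name for r in results_nis}
    if not (names_d == names_i == names_n):
        raise ValueError("the three analyses cover different gene-set libraries")

    by_d = {r.set_name: r for r in results_diff}
    sig_i = {r.set_name for r in results_is if r.fdr_q <= fdr}
    sig_n = {r.set_name for r in results_nis if r.fdr_q <= fdr}

    out: list[PostulateClass] = []
    for name in sorted(names_d):
        r = by_d[name]
        in_i, in_n = name in sig_i, name in sig_n
        if r.fdr_q <= fdr:
            tail = "WPD" if r.es >= 0 else "WND"
            if in_i and in_n:
                sub = "v_IS+NIS"
            elif in_i:
                sub = "v_IS-only"
            elif in_n:
                sub = "v_NIS-only"
            else:
                sub = "v_notIS/NIS"
            cat = f"{tail}[{sub}]"
        else:
            if in_i and in_n:
                cat = "not-significant-in-cGSEA[both]"
            elif in_i:
                cat = "not-significant-in-cGSEA[IS-only]"
            elif in_n:
                cat = "not-significant-in-cGSEA[NIS-only]"
            else:
                cat = "not-significant"
        out.append(PostulateClass(set_name=name, category=cat))
    return out
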