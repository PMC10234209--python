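"""Genomics x transcriptomics integration.

Expression counts are normalised to CPM with TMM scaling factors (trimmed
mean of M-values between each library and a reference library), lowly
expressed genes are removed, genes are ranked by the average F_AT of their
top-decile most differentiated nearby SNPs, and the concordance of the
genomic and transcriptomic rankings is tested threshold-free with
rank-rank hypergeometric overlap (RRHO) plus set-overlap and
region-enrichment Fisher tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .candidates import FLANK_DEFAULT, MultiSetResult, multiset_exact_test


# ---------------------------------------------------------------------------
# CPM / TMM
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame        # genes x samples, raw
    lib_sizes: pd.Series
    tmm_factors: pd.Series
    cpm: pd.DataFrame
    reference_sample: str


def _tmm_factor(obs: np.ndarray, ref: np.ndarray,
                lib_obs: float, lib_ref: float,
                logratio_trim: float = 0.30,
                abundance_trim: float = 0.05) -> float:
    """TMM scaling factor of one library against the reference library:
    2 ** (trimmed mean of per-gene log2 ratios M), trimming the most extreme
    30% of M values and 5% of A values from each tail."""
    both = (obs > 0) & (ref > 0)
    o, r = obs[both] / lib_obs, ref[both] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    if len(M) == 0:
        return 1.0
    lo_m, hi_m = np.quantile(M, [logratio_trim, 1 - logratio_trim])
    lo_a, hi_a = np.quantile(A, [abundance_trim, 1 - abundance_trim])
    keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
    if not keep.any():
        return 1.0
    return float(2.0 ** np.mean(M[keep]))


def cpm_tmm(counts: pd.DataFrame) -> ExpressionMatrix:
    """CPM with TMM normalisation.

    The reference library is the sample whose 75th-percentile count
    fraction is closest to the mean of those fractions; its factor is 1 by
    construction. CPM = count / (library size x factor) x 1e6, so zero
    counts stay zero.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero libraries: {bad}")
    q75 = counts.quantile(0.75, axis=0) / lib
    ref_sample = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)

    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_factor(counts[s].to_numpy(dtype=float), ref,
                                     lib[s], lib[ref_sample])
    f = pd.Series(factors)[counts.columns]
    cpm = counts / (lib * f) * 1e6
    return ExpressionMatrix(counts=counts, lib_sizes=lib, tmm_factors=f,
                            cpm=cpm, reference_sample=ref_sample)


def low_expression_filter(expr: ExpressionMatrix, cpm_max: float = 2.0,
                          n_samples: int = 9,
                          keep_mode: bool = False) -> list[str]:
    """Genes retained after the low-expression rule.

    Default (as printed): a gene is REMOVED iff it has <= cpm_max CPM in >=
    n_samples samples. ``keep_mode`` switches to the conventional dialect:
    keep a gene iff it has > cpm_max CPM in >= n_samples samples.
    """
    low = (expr.cpm <= cpm_max).sum(axis=1)
    if keep_mode:
        high = (expr.cpm > cpm_max).sum(axis=1)
        kept = high >= n_samples
    else:
        kept = low < n_samples
    return list(expr.cpm.index[kept])


# ---------------------------------------------------------------------------
# F_AT-based gene ranking
# ---------------------------------------------------------------------------

def rank_genes_by_fst(theta: pd.Series, genes: list[GeneModel],
                      flank: int = FLANK_DEFAULT,
                      top_frac: float = 0.10,
                      chrom: str | None = None) -> pd.DataFrame:
    """Rank genes by the mean theta of their top-``top_frac`` most
    differentiated SNPs within span +- flank (at least one SNP); genes
    without SNPs are excluded. Ties break by gene id (stable order)."""
    pos = theta.index.to_numpy(dtype=np.int64)
    vals = theta.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    pos, vals = pos[ok], vals[ok]
    order = np.argsort(pos)
    pos, vals = pos[order], vals[order]
    rows = []
    for g in genes:
        if chrom is not None and g.chrom != chrom:
            continue
        i = np.searchsorted(pos, g.start - flank, side="left")
        j = np.searchsorted(pos, g.end + flank, side="right")
        if j <= i:
            continue
        sub = np.sort(vals[i:j])[::-1]
        k = max(1, int(np.ceil(top_frac * len(sub))))
        rows.append((g.gene_id, float(sub[:k].mean()), len(sub)))
    df = pd.DataFrame(rows, columns=["gene_id", "score", "n_snps"])
    df = df.sort_values(["score", "gene_id"],
                        ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# RRHO
# ---------------------------------------------------------------------------

@dataclass
class RRHOGrid:
    universe: list[str]
    step: int
    thresholds: np.ndarray       # rank cutoffs per axis
    neg_log_p: np.ndarray        # matrix over (i from list A, j from list B)
    overlap: np.ndarray          # overlap counts per cell
    optimal_cell: tuple[int, int]  # rank cutoffs of the best cell
    optimal_genes: set[str]
    optimal_p: float


def rrho(list_a: list[str], list_b: list[str], step: int = 1) -> RRHOGrid:
    """Rank-rank hypergeometric overlap of two rankings of one universe.

    Cell (i, j): k = |top-i of A intersect top-j of B|; one-sided enrichment
    p = P(X >= k) for X ~ Hypergeometric(N, i, j). The optimal cell is the
    maximum of -log10 p; its overlapping gene set is returned.
    """
    if set(list_a) != set(list_b):
        raise ValueError("rankings must cover identical gene universes")
    if len(set(list_a)) != len(list_a):
        raise ValueError("duplicate genes in ranking")
    N = len(list_a)
    rank_b = {g: r for r, g in enumerate(list_b, start=1)}
    thresholds = np.arange(step, N + 1, step)
    if thresholds[-1] != N:
        thresholds = np.append(thresholds, N)
    m = len(thresholds)

    # overlap(i_cell, j_cell) via a 2-D cumulative count of rank pairs
    grid = np.zeros((m, m), dtype=np.int64)
    for r_a, g in enumerate(list_a, start=1):
        ia = np.searchsorted(thresholds, r_a, side="left")
        ib = np.searchsorted(thresholds, rank_b[g], side="left")
        grid[ia, ib] += 1
    overlap = np.cumsum(np.cumsum(grid, axis=0), axis=1)

    I = thresholds[:, None].astype(float)
    J = thresholds[None, :].astype(float)
    p = stats.hypergeom.sf(overlap - 1, N, I, J)
    neg = -np.log10(np.maximum(p, np.finfo(float).tiny))

    best = np.unravel_index(int(np.argmax(neg)), neg.shape)
    i_opt, j_opt = int(thresholds[best[0]]), int(thresholds[best[1]])
    top_a = set(list_a[:i_opt])
    top_b = set(list_b[:j_opt])
    return RRHOGrid(universe=list(list_a), step=step, thresholds=thresholds,
                    neg_log_p=neg, overlap=overlap,
                    optimal_cell=(i_opt, j_opt),
                    optimal_genes=top_a & top_b,
                    optimal_p=float(p[best]))


# ---------------------------------------------------------------------------
# Overlap and region tests
# ---------------------------------------------------------------------------

def overlap_set_test(gene_sets: list[set], background: set) -> MultiSetResult:
    """Exact intersection test for candidate gene sets over a shared
    background (genes identified in all data sets)."""
    return multiset_exact_test(gene_sets, background)


def region_enrichment_fet(gene_set: set, all_genes: list[GeneModel],
                          region: tuple[int, int],
                          chrom: str | None = None) -> dict:
    """Two-sided FET for enrichment of a gene set inside a genomic region
    (gene midpoint inside [region]); returns p and odds ratio."""
    if not gene_set:
        raise ValueError("empty gene set")
    rows = []
    for g in all_genes:
        if chrom is not None and g.chrom != chrom:
            continue
        mid = (g.start + g.end) // 2
        rows.append((g.gene_id in gene_set,
                     region[0] <= mid <= region[1]))
    t = np.zeros((2, 2), dtype=int)
    for in_set, in_region in rows:
        t[0 if in_set else 1, 0 if in_region else 1] += 1
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return {"p": float(p), "odds_ratio": float(odds),
            "table": t, "n_genes": len(rows)}
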