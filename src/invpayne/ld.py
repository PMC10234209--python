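"""Linkage disequilibrium: pairwise r2, SNP-vs-inversion LD, seeded SNP
subsampling, and the expected-r2 decay fit with a nested-model deviance test.

r2 is the squared allele-frequency correlation between two biallelic loci
computed on complete-case haplotypes. The decay of E(r2) with distance is
modelled by the classic drift-sampling expectation

    E(r2) = [(10+C) / ((2+C)(11+C))] *
            [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C))]

where C = rho * d is the population-scaled recombination rate (rho = 4 N_e r
per bp) times the distance in bp and n the sample size. Karyotype
differences in decay are tested by comparing a pooled fit (one rho) against
a per-group fit with an extra-sum-of-squares F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import MISSING, HaplotypeMatrix

MAF_DEFAULT = 0.1


# ---------------------------------------------------------------------------
# r2
# ---------------------------------------------------------------------------

def r2_pair(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r2 between two sites over complete-case haplotypes.

    r2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)); NaN when either site
    is monomorphic after complete-case filtering.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    n = len(a)
    if n < 2:
        return np.nan
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan
    pab = (a * b).mean()
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def maf_filter(matrix: HaplotypeMatrix, maf_min: float = MAF_DEFAULT
               ) -> np.ndarray:
    """Boolean site mask: minor allele frequency >= maf_min on the analysed
    sample set (non-missing haplotypes)."""
    c1, n = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = c1 / n
    maf = np.minimum(p, 1 - p)
    return (n >= 2) & (maf >= maf_min)


def sample_snps(matrix: HaplotypeMatrix, n: int = 5000,
                maf_min: float = MAF_DEFAULT,
                region: tuple[int, int] | None = None,
                seed: int = 0) -> np.ndarray:
    """Seeded uniform draw (without replacement) of qualifying site indices.

    If fewer than n sites qualify, all are returned with a warning.
    """
    ok = maf_filter(matrix, maf_min)
    if region is not None:
        ok &= matrix.region_mask(*region)
    idx = np.flatnonzero(ok)
    if len(idx) <= n:
        if len(idx) < n:
            warnings.warn(f"only {len(idx)} SNPs qualify (requested {n})")
        return idx
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(idx, size=n, replace=False))


def ld_decay_pairs(matrix: HaplotypeMatrix, subset: np.ndarray,
                   max_dist: int = 100_000) -> pd.DataFrame:
    """All unordered pairs (i < j) among ``subset`` sites within
    ``max_dist`` bp, with distance and r2."""
    sub = matrix.take_sites(np.asarray(subset))
    pos = sub.positions
    A = sub.alleles
    rows = []
    for i in range(len(pos)):
        j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
        for j in range(i + 1, j_hi):
            r2 = r2_pair(A[:, i], A[:, j])
            if not np.isnan(r2):
                rows.append((int(pos[i]), int(pos[j]),
                             int(pos[j] - pos[i]), r2))
    return pd.DataFrame(rows, columns=["pos_i", "pos_j", "distance", "r2"])


def snp_inversion_r2(matrix: HaplotypeMatrix, karyotypes: np.ndarray,
                     maf_min: float = 0.0) -> pd.Series:
    """r2 between every polymorphic SNP and the inversion, treating
    karyotype (INV/STD homokaryotypes only) as a biallelic pseudo-locus."""
    kary = np.asarray(karyotypes)
    keep = np.isin(kary, ("INV", "STD"))
    if not keep.all():
        matrix = matrix.take_samples(
            [s for s, k in zip(matrix.sample_ids, keep) if k])
        kary = kary[keep]
    pseudo = (kary == "INV").astype(np.int8)
    ok = maf_filter(matrix, maf_min) if maf_min > 0 else np.ones(
        matrix.n_sites, dtype=bool)
    vals = np.full(matrix.n_sites, np.nan)
    for j in np.flatnonzero(ok):
        vals[j] = r2_pair(matrix.alleles[:, j], pseudo)
    return pd.Series(vals, index=matrix.positions, name="r2_inversion")


# ---------------------------------------------------------------------------
# Expected r2 decay
# ---------------------------------------------------------------------------

def hill_expected_r2(C, n: int):
    """Expected r2 at scaled recombination distance C for sample size n."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    first = (10 + C) / ((2 + C) * (11 + C))
    second = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    out = first * second
    return float(out) if out.ndim == 0 else out


@dataclass
class HillFit:
    rho: dict            # group label -> per-bp rho estimate (grouped model)
    rho_pooled: float
    n: dict              # group label -> sample size used in E(r2)
    rss_pooled: float
    rss_grouped: float
    F: float
    p: float
    df: tuple[int, int]
    boundary: bool       # any rho estimate clipped at the 0 boundary


def _fit_rho(dist: np.ndarray, r2: np.ndarray, n: int) -> tuple[float, float]:
    """Least-squares rho >= 0 for one curve; returns (rho_hat, rss)."""

    def resid(log_rho: np.ndarray) -> np.ndarray:
        return hill_expected_r2(np.exp(log_rho[0]) * dist, n) - r2

    # coarse grid in log space, then local refinement
    grid = np.linspace(np.log(1e-9), np.log(1e-1), 40)
    rss_grid = [float(np.sum(resid(np.array([g])) ** 2)) for g in grid]
    x0 = grid[int(np.argmin(rss_grid))]
    sol = optimize.least_squares(resid, x0=[x0], method="lm", max_nfev=2000)
    if not sol.success:
        raise RuntimeError(f"rho fit failed: {sol.message}")
    rho = float(np.exp(sol.x[0]))
    rss = float(np.sum(sol.fun**2))
    return rho, rss


def fit_ld_decay(pairs_by_group: dict[str, pd.DataFrame],
                 n_by_group: dict[str, int],
                 min_pairs: int = 30) -> HillFit:
    """Fit rho pooled across groups vs per-group, and compare by an
    extra-sum-of-squares F test (the analysis-of-deviance for nested
    least-squares models).

    Each group's expected-r2 curve uses that group's own sample size n.
    """
    groups = sorted(pairs_by_group)
    for g in groups:
        if len(pairs_by_group[g]) < min_pairs:
            raise ValueError(f"group {g!r} has fewer than {min_pairs} pairs")
        if g not in n_by_group:
            raise ValueError(f"missing sample size for group {g!r}")

    # pooled: one rho, residuals use each group's n
    dist_all = [pairs_by_group[g]["distance"].to_numpy(float) for g in groups]
    r2_all = [pairs_by_group[g]["r2"].to_numpy(float) for g in groups]

    def pooled_resid(log_rho: np.ndarray) -> np.ndarray:
        rho = np.exp(log_rho[0])
        return np.concatenate([
            hill_expected_r2(rho * d, n_by_group[g]) - y
            for g, d, y in zip(groups, dist_all, r2_all)])

    grid = np.linspace(np.log(1e-9), np.log(1e-1), 40)
    rss_grid = [float(np.sum(pooled_resid(np.array([v])) ** 2)) for v in grid]
    sol = optimize.least_squares(pooled_resid,
                                 x0=[grid[int(np.argmin(rss_grid))]],
                                 method="lm", max_nfev=2000)
    if not sol.success:
        raise RuntimeError(f"pooled rho fit failed: {sol.message}")
    rho_pooled = float(np.exp(sol.x[0]))
    rss0 = float(np.sum(sol.fun**2))

    rho_g: dict[str, float] = {}
    rss1 = 0.0
    for g, d, y in zip(groups, dist_all, r2_all):
        rho_hat, rss = _fit_rho(d, y, n_by_group[g])
        # the grouped model nests the pooled one: never do worse per group
        rss_at_pooled = float(np.sum(
            (hill_expected_r2(rho_pooled * d, n_by_group[g]) - y) ** 2))
        if rss_at_pooled < rss:
            rho_hat, rss = rho_pooled, rss_at_pooled
        rho_g[g] = rho_hat
        rss1 += rss

    n_obs = sum(len(d) for d in dist_all)
    p0, p1 = 1, len(groups)
    df_num = p1 - p0
    df_den = n_obs - p1
    if df_den <= 0:
        raise ValueError("not enough pairs for the grouped model")
    # grouped model nests the pooled one; numerical fits can leave a
    # negligibly negative improvement
    improvement = max(rss0 - rss1, 0.0)
    if df_num == 0:  # single group: the models coincide, no test
        F, p = np.nan, np.nan
    elif rss1 > 0:
        F = (improvement / df_num) / (rss1 / df_den)
        p = float(stats.f.sf(F, df_num, df_den))
    else:
        F, p = np.inf, 0.0
    boundary = any(r < 1e-12 for r in rho_g.values()) or rho_pooled < 1e-12
    return HillFit(rho=rho_g, rho_pooled=rho_pooled, n=dict(n_by_group),
                   rss_pooled=rss0, rss_grouped=rss1, F=float(F), p=p,
                   df=(df_num, df_den), boundary=boundary)
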