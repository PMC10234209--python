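"""Genetic differentiation: per-SNP Weir-Cockerham F_ST, windowed averages,
the Karyotype / Geography / Geography+Karyotype comparison design, K_ST with
a permutation test, cross-continent inverted-chromosome comparisons, and the
one-way ANOVA + Tukey HSD summary over window values.

The estimator is the haploid variant of the Weir-Cockerham (1984)
variance-components theta: the data here are phased chromosomes, so each
haplotype is one observation and there is no within-individual component.

    MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
    MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
    n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

theta is 1 at a fixed difference, can be negative (estimator property), and
is undefined when both groups are monomorphic for the same allele. Between
karyotype classes the same quantity is conventionally called F_AT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, HaplotypeMatrix, SampleInfo
from .diversity import WINDOW_DEFAULT


# ---------------------------------------------------------------------------
# Per-site estimator
# ---------------------------------------------------------------------------

@dataclass
class FstSite:
    pos: int
    n1: int
    n2: int
    p1: float
    p2: float
    msp: float
    msg: float
    nc: float
    theta: float  # NaN when undefined


def wc_fst_components(counts: np.ndarray, sizes: np.ndarray
                      ) -> tuple[float, float, float, float]:
    """(MSP, MSG, nc, theta) for r groups given alternate-allele counts and
    non-missing sample sizes per group."""
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    r = len(sizes)
    if r < 2 or np.any(sizes < 2):
        return np.nan, np.nan, np.nan, np.nan
    p = counts / sizes
    n_tot = sizes.sum()
    p_bar = counts.sum() / n_tot
    msp = float(np.sum(sizes * (p - p_bar) ** 2) / (r - 1))
    msg = float(np.sum(sizes * p * (1 - p)) / np.sum(sizes - 1))
    nc = float((n_tot - np.sum(sizes**2) / n_tot) / (r - 1))
    denom = msp + (nc - 1) * msg
    theta = np.nan if denom == 0 else (msp - msg) / denom
    return msp, msg, nc, float(theta)


def wc_fst_site(counts1: tuple[int, int], counts2: tuple[int, int]) -> FstSite:
    """Weir-Cockerham theta at one site; counts are (alt, total non-missing)."""
    a1, n1 = counts1
    a2, n2 = counts2
    msp, msg, nc, theta = wc_fst_components(np.array([a1, a2]),
                                            np.array([n1, n2]))
    return FstSite(pos=0, n1=n1, n2=n2,
                   p1=a1 / n1 if n1 else np.nan,
                   p2=a2 / n2 if n2 else np.nan,
                   msp=msp, msg=msg, nc=nc, theta=theta)


def fst_series(matrix: HaplotypeMatrix, ids_a: list[str], ids_b: list[str],
               min_n: int = 2) -> pd.Series:
    """Per-site theta between two sample sets, indexed by position.

    Vectorised over sites; undefined sites (both groups monomorphic for the
    same allele, or fewer than ``min_n`` non-missing haplotypes in a group)
    are NaN.
    """
    A = matrix.take_samples(ids_a).alleles
    B = matrix.take_samples(ids_b).alleles
    nA = (A != MISSING).sum(axis=0).astype(float)
    nB = (B != MISSING).sum(axis=0).astype(float)
    cA = (A == 1).sum(axis=0).astype(float)
    cB = (B == 1).sum(axis=0).astype(float)
    ok = (nA >= max(min_n, 2)) & (nB >= max(min_n, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        pA, pB = cA / nA, cB / nB
        n_tot = nA + nB
        p_bar = (cA + cB) / n_tot
        msp = nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2  # r-1 = 1
        msg = (nA * pA * (1 - pA) + nB * pB * (1 - pB)) / (n_tot - 2)
        nc = n_tot - (nA**2 + nB**2) / n_tot
        denom = msp + (nc - 1) * msg
        theta = np.where(denom != 0, (msp - msg) / denom, np.nan)
    theta = np.where(ok, theta, np.nan)
    return pd.Series(theta, index=matrix.positions, name="theta")


# ---------------------------------------------------------------------------
# Comparison design
# ---------------------------------------------------------------------------

@dataclass
class ComparisonPlan:
    label: str                 # "K", "G" or "G+K"
    continent: str
    name: str                  # e.g. "FIFS"
    ids_a: list[str]
    ids_b: list[str]

    def __post_init__(self) -> None:
        if set(self.ids_a) & set(self.ids_b):
            raise ValueError(f"{self.name}: comparison sets overlap")


def _equalise(rng: np.random.Generator, a: list[str], b: list[str]
              ) -> tuple[list[str], list[str]]:
    k = min(len(a), len(b))
    return (list(rng.choice(a, size=k, replace=False)),
            list(rng.choice(b, size=k, replace=False)))


def build_comparison_plans(samples: SampleInfo, seed: int = 0,
                           equal_pools: bool = True) -> list[ComparisonPlan]:
    """For each continent with a low/high latitude pair build the three
    comparisons: K (low INV vs low STD), G (low STD vs high STD), G+K
    (low INV vs high STD). Heterokaryotypic and unknown samples never enter;
    karyotype pools are equal-size by default (50:50), seeded.
    """
    rng = np.random.default_rng(seed)
    plans: list[ComparisonPlan] = []
    t = samples.table
    t = t[t["karyotype"].isin(("INV", "STD"))]
    for continent, sub in t.groupby("continent", sort=True):
        low = sub[sub["latitude_class"] == "low"]
        high = sub[sub["latitude_class"] == "high"]
        low_inv = list(low[low["karyotype"] == "INV"]["sample_id"])
        low_std = list(low[low["karyotype"] == "STD"]["sample_id"])
        high_std = list(high[high["karyotype"] == "STD"]["sample_id"])
        if low_inv and low_std:
            a, b = (_equalise(rng, low_inv, low_std) if equal_pools
                    else (low_inv, low_std))
            plans.append(ComparisonPlan("K", continent, "K", a, b))
        if low_std and high_std:
            plans.append(ComparisonPlan("G", continent, "G",
                                        list(low_std), list(high_std)))
        if low_inv and high_std:
            plans.append(ComparisonPlan("G+K", continent, "G+K",
                                        list(low_inv), list(high_std)))
    return plans


def windowed_fst(plans: list[ComparisonPlan], matrix: HaplotypeMatrix,
                 window: int = WINDOW_DEFAULT,
                 span: tuple[int, int] | None = None) -> pd.DataFrame:
    """Unweighted mean of defined per-SNP theta in non-overlapping windows,
    per comparison plan; negatives retained, empty windows are NaN."""
    if span is None:
        span = (1, int(matrix.positions.max()) if matrix.n_sites else 1)
    frames = []
    for plan in plans:
        theta = fst_series(matrix, plan.ids_a, plan.ids_b)
        frames.append(windowed_theta(theta, matrix.chrom, window, span)
                      .assign(plan=plan.label, continent=plan.continent))
    return pd.concat(frames, ignore_index=True)


def windowed_theta(theta: pd.Series, chrom: str,
                   window: int = WINDOW_DEFAULT,
                   span: tuple[int, int] | None = None) -> pd.DataFrame:
    """Window a per-SNP theta series (mean over defined SNPs per window)."""
    pos = theta.index.to_numpy(dtype=np.int64)
    vals = theta.to_numpy(dtype=float)
    if span is None:
        span = (1, int(pos.max()) if len(pos) else 1)
    rows = []
    start = ((span[0] - 1) // window) * window + 1
    while start <= span[1]:
        end = min(start + window - 1, span[1])
        sel = (pos >= start) & (pos <= end) & ~np.isnan(vals)
        n_snps = int(sel.sum())
        value = float(vals[sel].mean()) if n_snps else np.nan
        rows.append((chrom, start, end, "fst", value, n_snps))
        start += window
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic",
                                       "value", "n_snps"])


# ---------------------------------------------------------------------------
# K_ST
# ---------------------------------------------------------------------------

def pairwise_differences(matrix: HaplotypeMatrix) -> np.ndarray:
    """n x n matrix of pairwise difference counts over complete-case sites."""
    a = matrix.alleles
    n = matrix.n_samples
    diff = np.zeros((n, n))
    valid = a != MISSING
    for i in range(n):
        both = valid[i] & valid
        neq = (a[i] != a) & both
        diff[i] = neq.sum(axis=1)
    return diff


def kst_region(matrix: HaplotypeMatrix, ids_a: list[str], ids_b: list[str],
               n_perm: int = 1000, seed: int = 0) -> dict:
    """Hudson-style K_ST between two groups with a permutation p-value.

    K_S is the sample-size weighted mean of the two within-group mean
    pairwise difference counts, K_T the mean over all pairs; K_ST = 1 -
    K_S/K_T. p is the fraction of label permutations with K_ST at least as
    large (with the +1 correction).
    """
    ids = list(ids_a) + list(ids_b)
    sub = matrix.take_samples(ids)
    D = pairwise_differences(sub)
    n1, n2 = len(ids_a), len(ids_b)
    labels = np.array([0] * n1 + [1] * n2)

    def kst(lbl: np.ndarray) -> float:
        i1 = np.flatnonzero(lbl == 0)
        i2 = np.flatnonzero(lbl == 1)
        k1 = D[np.ix_(i1, i1)][np.triu_indices(len(i1), 1)].mean()
        k2 = D[np.ix_(i2, i2)][np.triu_indices(len(i2), 1)].mean()
        kt = D[np.triu_indices(len(lbl), 1)].mean()
        ks = (len(i1) * k1 + len(i2) * k2) / len(lbl)
        return 1.0 - ks / kt if kt > 0 else 0.0

    obs = kst(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    lbl = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lbl)
        if kst(lbl) >= obs:
            hits += 1
    return {"KS": float((n1 * D[np.ix_(range(n1), range(n1))]
                         [np.triu_indices(n1, 1)].mean()
                         + n2 * D[np.ix_(range(n1, n1 + n2), range(n1, n1 + n2))]
                         [np.triu_indices(n2, 1)].mean()) / (n1 + n2)),
            "KT": float(D[np.triu_indices(n1 + n2, 1)].mean()),
            "KST": float(obs),
            "p": (1 + hits) / (1 + n_perm)}


# ---------------------------------------------------------------------------
# Cross-continent inverted chromosomes
# ---------------------------------------------------------------------------

def inverted_cross_continent_fst(matrices: dict[str, HaplotypeMatrix],
                                 window: int = WINDOW_DEFAULT,
                                 span: tuple[int, int] | None = None
                                 ) -> pd.DataFrame:
    """Windowed theta for all population pairs of inverted chromosomes,
    restricted to SNPs shared (genotyped) across all populations."""
    if len(matrices) < 2:
        raise ValueError("need at least two populations")
    shared = None
    for m in matrices.values():
        pos = set(m.positions.tolist())
        shared = pos if shared is None else (shared & pos)
    shared = np.array(sorted(shared), dtype=np.int64)
    if len(shared) == 0:
        raise ValueError("no shared SNPs across populations")
    frames = []
    pops = sorted(matrices)
    subs = {p: matrices[p].take_sites(np.isin(matrices[p].positions, shared))
            for p in pops}
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            ma, mb = subs[pa], subs[pb]
            nA = (ma.alleles != MISSING).sum(axis=0).astype(float)
            nB = (mb.alleles != MISSING).sum(axis=0).astype(float)
            cA = (ma.alleles == 1).sum(axis=0).astype(float)
            cB = (mb.alleles == 1).sum(axis=0).astype(float)
            theta = np.full(len(shared), np.nan)
            for j in range(len(shared)):
                if nA[j] >= 2 and nB[j] >= 2:
                    theta[j] = wc_fst_components(
                        np.array([cA[j], cB[j]]), np.array([nA[j], nB[j]]))[3]
            series = pd.Series(theta, index=shared)
            frames.append(windowed_theta(series, ma.chrom, window, span)
                          .assign(pair=f"{pa}-{pb}"))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# ANOVA + Tukey over window values
# ---------------------------------------------------------------------------

def fst_anova_tukey(windows: pd.DataFrame, value_col: str = "value",
                    label_col: str = "plan") -> dict:
    """One-way ANOVA of window values on the comparison label, plus Tukey
    HSD contrasts. Requires >= 2 labels with >= 2 windows each."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    w = windows.dropna(subset=[value_col])
    groups = {k: g[value_col].to_numpy() for k, g in w.groupby(label_col)}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two comparison labels")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each label needs at least two windows")
    F, p = stats.f_oneway(*groups.values())
    tk = pairwise_tukeyhsd(w[value_col].to_numpy(), w[label_col].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=tk.summary().data[0])
    return {"F": float(F), "p": float(p), "tukey": tukey}
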