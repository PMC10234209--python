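"""Candidate SNP/gene calling and enrichment machinery.

Candidate SNPs are positions whose between-karyotype F_AT reaches a
threshold (>= 0.9 by default); candidate genes are genes with at least one
candidate SNP inside the gene span or within 2 kb of either end (the
flanking windows harbour regulatory elements). Sharing of candidates across
populations is assessed with an exact multi-set intersection test; GO
enrichment uses a SNP-resampling permutation null that controls for gene
length (long genes collect SNPs by chance); SNP functional classes are
tested with Fisher's exact tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MISSING, GeneModel, HaplotypeMatrix, SampleInfo

FLANK_DEFAULT = 2000
FST_THRESHOLD = 0.9


# ---------------------------------------------------------------------------
# Candidate calling and gene mapping
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    origin: str
    snps: list[int]                  # positions
    genes: set[str] = field(default_factory=set)
    threshold: float = FST_THRESHOLD


def call_candidate_snps(theta: pd.Series, origin: str = "NA",
                        threshold: float = FST_THRESHOLD) -> CandidateSet:
    """Positions with theta >= threshold (inclusive); undefined excluded."""
    vals = theta.to_numpy(dtype=float)
    keep = ~np.isnan(vals) & (vals >= threshold)
    return CandidateSet(origin=origin,
                        snps=[int(p) for p in theta.index[keep]],
                        threshold=threshold)


def map_snps_to_genes(snps: list[int], genes: list[GeneModel],
                      flank: int = FLANK_DEFAULT,
                      chrom: str | None = None) -> set[str]:
    """Genes whose [start - flank, end + flank] span contains a SNP;
    multi-mapping to overlapping genes is allowed."""
    if not snps:
        return set()
    pos = np.sort(np.asarray(snps, dtype=np.int64))
    hit = set()
    for g in genes:
        if chrom is not None and g.chrom != chrom:
            continue
        lo, hi = g.start - flank, g.end + flank
        i = np.searchsorted(pos, lo, side="left")
        if i < len(pos) and pos[i] <= hi:
            hit.add(g.gene_id)
    return hit


# ---------------------------------------------------------------------------
# Multi-set exact intersection test
# ---------------------------------------------------------------------------

@dataclass
class MultiSetResult:
    sizes: list[int]
    background: int
    observed: int
    expected: float
    p: float
    pmf: np.ndarray  # distribution of the m-fold intersection size


def multiset_exact_test(sets: list[set], background: set) -> MultiSetResult:
    """Exact upper-tail test for the size of the intersection of m sets
    drawn uniformly from a common background of size N.

    The intersection is built sequentially: conditional on the running
    intersection having size j, its overlap with the next (uniformly placed)
    set of size n is hypergeometric(N, j, n). Mixing over these conditionals
    yields the exact distribution of the final intersection size.
    E = prod(n_i) / N^(m-1).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    N = len(background)
    for i, s in enumerate(sets):
        if not s <= background:
            raise ValueError(f"set {i} is not a subset of the background")
    sizes = [len(s) for s in sets]
    obs = len(set.intersection(*sets))

    # law of |S1 n S2|, then mix in the remaining sets one at a time
    k = np.arange(min(sizes[0], sizes[1]) + 1)
    dist = stats.hypergeom.pmf(k, N, sizes[0], sizes[1])
    for n_next in sizes[2:]:
        new = np.zeros(min(len(dist) - 1, n_next) + 1)
        for j in np.flatnonzero(dist > 0):
            kk = np.arange(0, min(j, n_next) + 1)
            new[kk] += dist[j] * stats.hypergeom.pmf(kk, N, j, n_next)
        dist = new
    expected = float(np.prod([float(s) for s in sizes]) / N ** (len(sizes) - 1))
    p = float(dist[obs:].sum())
    return MultiSetResult(sizes=sizes, background=N, observed=obs,
                          expected=expected, p=min(p, 1.0), pmf=dist)


# ---------------------------------------------------------------------------
# GO permutation test (SNP-resampling, gene-abundance null)
# ---------------------------------------------------------------------------

def go_permutation_test(candidate_snps: list[int], all_snps: list[int],
                        genes: list[GeneModel], go_map: dict[str, set[str]],
                        flank: int = FLANK_DEFAULT,
                        n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-GO empirical enrichment p from a null of random SNP draws.

    Each permutation draws |candidates| SNPs uniformly (without replacement)
    from all_snps, maps them to genes (distinct genes counted once), and
    records the per-GO gene count. p = (1 + #perms >= observed)/(1+n_perm);
    q is Benjamini-Hochberg across GO terms. GO terms with no mappable gene
    are reported with missing p.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000 for stable tails")
    rng = np.random.default_rng(seed)
    all_pos = np.asarray(sorted(all_snps), dtype=np.int64)
    n_cand = len(candidate_snps)
    if n_cand == 0:
        raise ValueError("empty candidate set")

    # SNP -> gene indices (by position), gene -> GO membership matrix
    gene_ids = [g.gene_id for g in genes]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    starts = np.array([g.start - flank for g in genes])
    ends = np.array([g.end + flank for g in genes])
    snp_genes: list[np.ndarray] = []
    for p in all_pos:
        hits = np.flatnonzero((starts <= p) & (p <= ends))
        snp_genes.append(hits)
    pos_index = {int(p): i for i, p in enumerate(all_pos)}

    go_terms = sorted({t for ts in go_map.values() for t in ts})
    go_col = {t: j for j, t in enumerate(go_terms)}
    membership = np.zeros((len(genes), len(go_terms)), dtype=bool)
    for g, ts in go_map.items():
        gi = gene_index.get(g)
        if gi is not None:
            for t in ts:
                membership[gi, go_col[t]] = True
    mappable = membership.any(axis=0)

    def go_counts(snp_idx: np.ndarray) -> np.ndarray:
        gs = [snp_genes[i] for i in snp_idx if len(snp_genes[i])]
        if not gs:
            return np.zeros(len(go_terms), dtype=np.int64)
        genes_hit = np.unique(np.concatenate(gs))
        return membership[genes_hit].sum(axis=0)

    cand_idx = np.array([pos_index[p] for p in candidate_snps])
    observed = go_counts(cand_idx)

    exceed = np.zeros(len(go_terms), dtype=np.int64)
    for _ in range(n_perm):
        draw = rng.choice(len(all_pos), size=n_cand, replace=False)
        exceed += go_counts(draw) >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(mappable, p, np.nan)
    q = np.full_like(p, np.nan)
    if mappable.any():
        q[mappable] = multipletests(p[mappable], method="fdr_bh")[1]
    return pd.DataFrame({"go": go_terms, "observed_genes": observed,
                         "p": p, "q": q, "mappable": mappable})


# ---------------------------------------------------------------------------
# SNP functional-class enrichment
# ---------------------------------------------------------------------------

SNP_CLASSES = ("intergenic_region", "upstream_gene_variant",
               "5_prime_UTR_variant", "intron_variant", "synonymous_variant",
               "missense_variant", "3_prime_UTR_variant",
               "downstream_gene_variant")


def snp_class_enrichment(candidate_snps: set[int],
                         snp_classes: pd.DataFrame,
                         classes: tuple[str, ...] = SNP_CLASSES
                         ) -> pd.DataFrame:
    """Two-sided Fisher's exact test per functional class with Bonferroni
    correction over the tested classes.

    snp_classes columns: pos, snp_class. A class with zero SNPs gets p = 1.
    """
    is_cand = snp_classes["pos"].isin(candidate_snps).to_numpy()
    rows = []
    for cls in classes:
        in_cls = (snp_classes["snp_class"] == cls).to_numpy()
        a = int(np.sum(is_cand & in_cls))
        b = int(np.sum(is_cand & ~in_cls))
        c = int(np.sum(~is_cand & in_cls))
        d = int(np.sum(~is_cand & ~in_cls))
        if a + c == 0:
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")
        rows.append((cls, a, b, c, d, odds, p,
                     min(1.0, p * len(classes))))
    return pd.DataFrame(rows, columns=["snp_class", "cand_in", "cand_out",
                                       "noncand_in", "noncand_out",
                                       "odds_ratio", "p", "p_bonferroni"])


# ---------------------------------------------------------------------------
# Inversion-specific allele profiling
# ---------------------------------------------------------------------------

def inversion_allele_profile(matrix: HaplotypeMatrix, samples: SampleInfo,
                             candidate_positions: list[int],
                             ref_population: str,
                             min_diff: float = 0.5) -> dict:
    """Median frequency of the inversion-associated ('focal') allele per
    (population, karyotype), plus positions with a large INV-STD frequency
    difference in the reference population.

    The focal allele per candidate SNP is the allele more frequent among INV
    than STD chromosomes of ``ref_population``. Returns medians over SNPs
    and the positions with |freq(INV) - freq(STD)| >= min_diff in the
    reference population.
    """
    if not candidate_positions:
        raise ValueError("empty candidate set")
    pos_mask = np.isin(matrix.positions, np.asarray(candidate_positions))
    if not pos_mask.any():
        raise ValueError("no candidate positions present in matrix")
    sub = matrix.take_sites(pos_mask)

    def freqs(pop: str, kary: str) -> np.ndarray:
        ids = [s for s in samples.ids(population=pop, karyotype=kary)
               if s in sub.sample_ids]
        if not ids:
            return np.full(sub.n_sites, np.nan)
        a = sub.take_samples(ids).alleles
        with np.errstate(invalid="ignore", divide="ignore"):
            return (a == 1).sum(axis=0) / (a != MISSING).sum(axis=0)

    f_inv_ref = freqs(ref_population, "INV")
    f_std_ref = freqs(ref_population, "STD")
    focal_is_alt = f_inv_ref >= f_std_ref

    def focal_freq(f_alt: np.ndarray) -> np.ndarray:
        return np.where(focal_is_alt, f_alt, 1 - f_alt)

    pops = sorted(samples.table["population"].unique())
    medians = {}
    for pop in pops:
        for kary in ("INV", "STD"):
            f = focal_freq(freqs(pop, kary))
            if not np.all(np.isnan(f)):
                medians[(pop, kary)] = float(np.nanmedian(f))
    diff = np.abs(f_inv_ref - f_std_ref)
    big = sub.positions[~np.isnan(diff) & (diff >= min_diff)]
    return {"medians": medians,
            "focal_is_alt": pd.Series(focal_is_alt, index=sub.positions),
            "divergent_positions": [int(p) for p in big]}
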