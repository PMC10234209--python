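"""Reconstruction of maternal wild-type haplotypes from F1 hemiclone
sequencing, by contrasting F1 allele counts with a pooled sire reference.

Each F1 library is a diploid of one maternal wild-type chromosome over one
sire chromosome; where the sire pool is homozygous, any non-pool allele seen
at credible frequency in the F1 must be the maternal allele. The filter
cascade:

* pool sites are usable only when effectively homozygous (minor allele
  fraction < 10% in the pool);
* a non-pool allele is reported only if its summed count across all F1
  samples is >= 10;
* within a library, an allele must fall inside the central 90% exact
  binomial interval around the expected heterozygous frequency of 50%;
* library sites with coverage < 15, or above that sample's 95th coverage
  percentile on the chromosome, are masked (false negatives from shallow
  sampling, false positives from paralogous mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, HaplotypeMatrix

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PhasingParams:
    pool_max_maf: float = 0.10
    min_wild_allele_count: int = 10
    ci_level: float = 0.90
    het_expectation: float = 0.5
    min_cov: int = 15
    max_cov_quantile: float = 0.95
    per_sample_min_count: bool = False  # dialect: apply the count-10 rule per sample

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")


# ---------------------------------------------------------------------------
# Pool genotyping
# ---------------------------------------------------------------------------

def call_pool_homozygous(pool_counts: pd.DataFrame,
                         params: PhasingParams = PhasingParams()
                         ) -> pd.DataFrame:
    """Classify pool sites as usable (effectively homozygous) and return the
    pool major allele.

    ``pool_counts`` columns: chrom pos A C G T. A site is usable iff its
    pool minor-allele fraction (all non-major reads) is < pool_max_maf;
    zero-coverage sites are unusable and reported as such.
    """
    counts = pool_counts[list(BASES)].to_numpy(dtype=np.int64)
    total = counts.sum(axis=1)
    major_idx = counts.argmax(axis=1)
    major = counts[np.arange(len(counts)), major_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, (total - major) / total, np.nan)
    usable = (total > 0) & (maf < params.pool_max_maf)
    out = pool_counts[["chrom", "pos"]].copy()
    out["usable"] = usable
    out["pool_allele"] = np.array(BASES)[major_idx]
    out.loc[total == 0, "pool_allele"] = "N"
    out["coverage"] = total
    return out


# ---------------------------------------------------------------------------
# Binomial CI
# ---------------------------------------------------------------------------

def binomial_ci_bounds(coverage: int, p: float = 0.5,
                       level: float = 0.90) -> tuple[int, int]:
    """Central exact binomial count interval [lo, hi] (inclusive pass).

    lo is the largest k with CDF(k-1) <= alpha/2 and hi the smallest k with
    1 - CDF(k) <= alpha/2, alpha = 1 - level.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    alpha = 1.0 - level
    k = np.arange(coverage + 1)
    cdf = stats.binom.cdf(k, coverage, p)
    # lo: largest k such that P(X < k) <= alpha/2
    below = np.concatenate([[0.0], cdf[:-1]])  # P(X <= k-1)
    lo = int(k[below <= alpha / 2].max())
    above = 1.0 - cdf  # P(X > k)
    hi = int(k[above <= alpha / 2].min())
    return lo, hi


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

def phase_f1(counts: pd.DataFrame, pool_calls: pd.DataFrame,
             params: PhasingParams = PhasingParams()
             ) -> tuple[HaplotypeMatrix, pd.DataFrame]:
    """Reconstruct per-sample maternal haplotypes from F1 allele counts.

    ``counts`` columns: sample chrom pos A C G T (one row per sample x site).
    Returns a HaplotypeMatrix (allele 0 = pool allele, 1 = maternal non-pool
    allele, missing where masked) and a tidy mask table with the reason a
    call was withheld.
    """
    samples = sorted(counts["sample"].unique())
    if not samples:
        raise ValueError("no samples in counts table")
    pool = pool_calls.set_index("pos")
    chrom = counts["chrom"].iloc[0]

    # coverage thresholds per sample (per chromosome; one chromosome here)
    cov = counts[list(BASES)].sum(axis=1)
    counts = counts.assign(_cov=cov)
    cov_hi = counts.groupby("sample")["_cov"].quantile(
        params.max_cov_quantile, interpolation="nearest")

    usable_pos = pool.index[pool["usable"]].to_numpy()
    usable_pos = np.intersect1d(usable_pos, counts["pos"].unique())
    pos_index = {p: j for j, p in enumerate(usable_pos)}
    n_sites = len(usable_pos)

    pool_allele = pool.loc[usable_pos, "pool_allele"].to_numpy()

    # genome-wide summed count of each non-pool allele across all F1 samples
    summed = counts.groupby("pos")[list(BASES)].sum()

    base_of = {b: i for i, b in enumerate(BASES)}
    wild_allele = np.array(["N"] * n_sites, dtype=object)
    for j, p in enumerate(usable_pos):
        row = summed.loc[p, list(BASES)].to_numpy(dtype=np.int64)
        row = row.copy()
        row[base_of[pool_allele[j]]] = 0
        if row.max() >= params.min_wild_allele_count:
            wild_allele[j] = BASES[int(row.argmax())]  # most frequent non-pool

    n = len(samples)
    alleles = np.full((n, n_sites), MISSING, dtype=np.int8)
    mask_rows = []
    ci_cache: dict[int, tuple[int, int]] = {}

    by_sample = dict(tuple(counts.groupby("sample")))
    for si, sample in enumerate(samples):
        sub = by_sample[sample]
        hi_thresh = cov_hi[sample]
        for _, row in sub.iterrows():
            p = row["pos"]
            j = pos_index.get(p)
            if j is None:
                continue
            coverage = int(row["_cov"])
            if coverage < params.min_cov:
                mask_rows.append((sample, p, "low_coverage"))
                continue
            if coverage > hi_thresh:
                mask_rows.append((sample, p, "high_coverage"))
                continue
            if coverage not in ci_cache:
                ci_cache[coverage] = binomial_ci_bounds(
                    coverage, params.het_expectation, params.ci_level)
            lo, hi = ci_cache[coverage]
            pool_b = pool_allele[j]
            wild_b = wild_allele[j]
            c_pool = int(row[pool_b])
            if wild_b != "N" and wild_b != pool_b:
                c_wild = int(row[wild_b])
                if params.per_sample_min_count and \
                        c_wild < params.min_wild_allele_count:
                    c_wild = 0
                if c_wild > 0 and lo <= c_wild <= hi:
                    alleles[si, j] = 1
                    continue
                if c_wild > 0:
                    # non-pool allele observed but outside the CI: ambiguous
                    mask_rows.append((sample, p, "outside_ci"))
                    continue
            # only the pool allele observed; accept it if its count is
            # consistent with homozygosity (i.e. not looking heterozygous)
            if c_pool == coverage or c_pool > hi:
                alleles[si, j] = 0
            else:
                mask_rows.append((sample, p, "ambiguous"))

    ref = [str(b) for b in pool_allele]
    alt = [w if w != "N" and w != r else ("T" if r != "T" else "A")
           for w, r in zip(wild_allele, ref)]
    matrix = HaplotypeMatrix(sample_ids=samples, chrom=chrom,
                             positions=usable_pos.astype(np.int64),
                             alleles=alleles, ref=ref, alt=alt)
    mask = pd.DataFrame(mask_rows, columns=["sample", "pos", "reason"])
    if (alleles == MISSING).all():
        import warnings
        warnings.warn("all sites masked; empty haplotypes returned")
    return matrix, mask
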