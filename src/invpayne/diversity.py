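"""Nucleotide diversity, Tajima's D, quality masks and 100-kb windows.

Statistics are computed from per-site sample allele configurations of a
HaplotypeMatrix. Windowed averages honour a per-position quality mask: the
denominator is the number of mask-pass positions in the window, not the
window length, so regions with poor data do not dilute the average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, HaplotypeMatrix, MaskTrack, SampleInfo

WINDOW_DEFAULT = 100_000

# Inversion geometry of the focal 3R polymorphism, reference coordinates.
INSIDE_SPAN = (16_432_209, 24_744_010)
BUFFER_SPAN = (14_232_209, 26_744_010)  # inversion extended by 2 Mb both ends


@dataclass(frozen=True)
class RegionSpec:
    """Inside / buffer-excluded / control-source geometry for one inversion."""

    chrom: str = "3R"
    inside: tuple[int, int] = INSIDE_SPAN
    buffer: tuple[int, int] = BUFFER_SPAN
    control_chroms: tuple[str, ...] = ("3L", "3R")

    def __post_init__(self) -> None:
        if not (self.buffer[0] <= self.inside[0]
                and self.inside[1] <= self.buffer[1]):
            raise ValueError("inside span must lie within the buffer span")


@dataclass
class TajimaResult:
    n: int
    S: int
    k_hat: float          # mean pairwise differences, summed over sites
    theta_w: float        # S / a1
    D: float | None       # None when undefined (S == 0)
    constants: dict


# ---------------------------------------------------------------------------
# Per-site pi
# ---------------------------------------------------------------------------

def site_pi(count_alt: int, n: int) -> float:
    """Mean pairwise difference at one biallelic site with ``count_alt``
    copies of one allele among ``n`` non-missing haplotypes: 2ab/(n(n-1))."""
    if n < 2:
        return math.nan
    a = count_alt
    b = n - a
    return 2.0 * a * b / (n * (n - 1))


def site_pi_series(matrix: HaplotypeMatrix, min_n: int = 2) -> pd.Series:
    """Per-site pi over the non-missing haplotypes, indexed by position."""
    c1, n = matrix.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c1 * (n - c1) / (n * (n - 1.0))
    pi = np.where(n >= max(min_n, 2), pi, np.nan)
    return pd.Series(pi, index=matrix.positions, name="pi")


# ---------------------------------------------------------------------------
# Quality mask construction
# ---------------------------------------------------------------------------

def build_quality_mask(chrom: str, span: tuple[int, int],
                       positions: np.ndarray,
                       fail_fraction: np.ndarray,
                       max_fail_fraction: float = 0.5) -> MaskTrack:
    """A position fails iff its failing-sample fraction is strictly greater
    than ``max_fail_fraction`` (a site where exactly half the samples fail
    still passes). Positions in the span that are not listed pass."""
    positions = np.asarray(positions, dtype=np.int64)
    fail_fraction = np.asarray(fail_fraction, dtype=float)
    if positions.shape != fail_fraction.shape:
        raise ValueError("positions and fail_fraction must align")
    if np.isnan(fail_fraction).any():
        raise ValueError("fail_fraction contains NaN (no samples at site?)")
    failing = positions[fail_fraction > max_fail_fraction]
    failing_set = set(int(p) for p in failing)
    # pass intervals = span minus failing positions
    intervals = []
    start = span[0]
    for p in sorted(failing_set):
        if p > start:
            intervals.append((start, p - 1))
        start = p + 1
    if start <= span[1]:
        intervals.append((start, span[1]))
    return MaskTrack(chrom, span, intervals)


def missingness_mask(matrix: HaplotypeMatrix, span: tuple[int, int] | None = None,
                     max_fail_fraction: float = 0.5) -> MaskTrack:
    """Quality mask from per-sample missingness at genotyped sites."""
    if span is None:
        span = (1, int(matrix.positions.max()) if matrix.n_sites else 1)
    frac = (matrix.alleles == MISSING).mean(axis=0)
    return build_quality_mask(matrix.chrom, span, matrix.positions, frac,
                              max_fail_fraction)


# ---------------------------------------------------------------------------
# Windowed averages
# ---------------------------------------------------------------------------

def window_average(values: pd.Series, mask: MaskTrack,
                   statistic: str = "pi",
                   window: int = WINDOW_DEFAULT,
                   span: tuple[int, int] | None = None) -> pd.DataFrame:
    """Average a per-position statistic in non-overlapping windows anchored
    at position 1.

    value = sum of the statistic over mask-pass positions in the window
    divided by the count of mask-pass positions (positions without an entry
    in ``values`` contribute 0 to the numerator: a pass position that is not
    a SNP has pi = 0). Windows with zero pass positions get NaN. The final
    partial window is retained.
    """
    if span is None:
        span = mask.span
    positions = values.index.to_numpy(dtype=np.int64)
    vals = values.to_numpy(dtype=float)
    keep = mask.passes(positions) & ~np.isnan(vals)
    positions, vals = positions[keep], vals[keep]

    rows = []
    start = ((span[0] - 1) // window) * window + 1
    while start <= span[1]:
        end = min(start + window - 1, span[1])
        n_valid = mask.n_pass_in(start, end)
        sel = (positions >= start) & (positions <= end)
        n_snps = int(sel.sum())
        value = vals[sel].sum() / n_valid if n_valid > 0 else np.nan
        rows.append((mask.chrom, start, end, statistic, value, n_valid, n_snps))
        start += window
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "statistic",
                                       "value", "n_valid_positions", "n_snps"])


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """The standard a1..e2 constants; depend only on sample size n."""
    if n < 3:
        raise ValueError("Tajima's D needs n >= 3 (variance undefined below)")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_sfs(n: int, S: int, k_hat: float) -> TajimaResult:
    """D from sample size, segregating sites and mean pairwise differences."""
    const = tajima_constants(n)
    theta_w = S / const["a1"]
    if S == 0:
        return TajimaResult(n, 0, k_hat, 0.0, None, const)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    d = (k_hat - theta_w) / math.sqrt(var)
    return TajimaResult(n, S, k_hat, theta_w, d, const)


def tajimas_d(matrix: HaplotypeMatrix,
              region: tuple[int, int] | None = None,
              min_n_fraction: float = 0.8) -> TajimaResult:
    """Tajima's D over a region of a haplotype matrix.

    Sites with missing data use the non-missing subset; the constants use
    the modal non-missing sample size and sites whose n falls below
    ``min_n_fraction`` x modal are dropped (their configurations are not
    comparable).
    """
    m = matrix if region is None else matrix.take_sites(
        matrix.region_mask(*region))
    c1, n = m.allele_counts()
    if len(n) == 0:
        return tajimas_d_from_sfs(max(matrix.n_samples, 3), 0, 0.0)
    modal_n = int(np.bincount(n[n > 0]).argmax()) if (n > 0).any() else 0
    if modal_n < 3:
        raise ValueError("fewer than 3 non-missing haplotypes at typical sites")
    keep = n >= min_n_fraction * modal_n
    c1, n = c1[keep], n[keep]
    seg = (c1 > 0) & (c1 < n)
    S = int(seg.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_sites = 2.0 * c1 * (n - c1) / (n * (n - 1.0))
    k_hat = float(np.nansum(pi_sites[seg]))
    return tajimas_d_from_sfs(modal_n, S, k_hat)


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

def partition_regions(windows: pd.DataFrame, spec: RegionSpec,
                      n_control: int | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Label windows 'inside' the inversion or as a seeded random 'control'
    sample of equal size drawn from outside the buffered interval.

    Inside = windows fully within spec.inside on spec.chrom. Control
    candidates are windows on any control chromosome that do not overlap the
    buffer interval on spec.chrom.
    """
    w = windows.copy()
    on_focal = w["chrom"] == spec.chrom
    inside = on_focal & (w["start"] >= spec.inside[0]) & (w["end"] <= spec.inside[1])
    in_buffer = on_focal & (w["end"] >= spec.buffer[0]) & (w["start"] <= spec.buffer[1])
    candidate = w["chrom"].isin(spec.control_chroms) & ~in_buffer
    if n_control is None:
        n_control = int(inside.sum())
    pool = np.flatnonzero(candidate.to_numpy())
    if len(pool) < n_control:
        raise ValueError(
            f"only {len(pool)} control windows available, need {n_control}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_control, replace=False)
    label = np.full(len(w), "other", dtype=object)
    label[inside.to_numpy()] = "inside"
    label[chosen] = "control"
    w["region"] = label
    return w


# ---------------------------------------------------------------------------
# Karyotype-pooled statistics
# ---------------------------------------------------------------------------

def karyotype_pooled_stats(matrix: HaplotypeMatrix, samples: SampleInfo,
                           mode: str = "equal", n_total: int | None = None,
                           seed: int = 0,
                           region: tuple[int, int] | None = None) -> TajimaResult:
    """Tajima's D for a pooled INV+STD subsample.

    mode='equal' draws a 50:50 karyotype pool; mode='proportional' draws
    karyotypes in proportion to their frequencies among homokaryotypes.
    """
    inv_ids = [s for s in samples.ids(karyotype="INV")
               if s in matrix.sample_ids]
    std_ids = [s for s in samples.ids(karyotype="STD")
               if s in matrix.sample_ids]
    if not inv_ids or not std_ids:
        raise ValueError("both INV and STD samples are required for pooling")
    rng = np.random.default_rng(seed)
    if mode == "equal":
        per = min(len(inv_ids), len(std_ids))
        if n_total is not None:
            per = min(per, n_total // 2)
        pick = (list(rng.choice(inv_ids, size=per, replace=False))
                + list(rng.choice(std_ids, size=per, replace=False)))
    elif mode == "proportional":
        total = n_total if n_total is not None else len(inv_ids) + len(std_ids)
        q = len(inv_ids) / (len(inv_ids) + len(std_ids))
        n_inv = int(round(q * total))
        n_inv = min(max(n_inv, 0), len(inv_ids))
        n_std = min(total - n_inv, len(std_ids))
        pick = (list(rng.choice(inv_ids, size=n_inv, replace=False))
                + list(rng.choice(std_ids, size=n_std, replace=False)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return tajimas_d(matrix.take_samples(pick), region=region)
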