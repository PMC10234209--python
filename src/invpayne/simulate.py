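"""Forward Wright--Fisher simulation of a balanced inversion polymorphism.

The model: a single panmictic population of N diploids (2N chromosomes), one
linear chromosome, and an inversion segregating at frequency q. Inversion
status is a per-chromosome label, never a coordinate rearrangement -- all
statistics downstream are computed in reference coordinates, so the only
things the inversion does mechanistically are

* suppress crossing over in heterokaryotypic individuals between the
  breakpoints (crossovers outside the inverted segment remain free),
* exchange single sites between the karyotype classes by gene conversion at
  a position-dependent per-site rate phi(x), minimal near the breakpoints
  and higher in the inversion body ("gene flux"),
* experience balancing selection, either as a symmetric heterokaryotype
  fitness advantage 1+s or as a deterministic clamp that restores the
  karyotype counts to q each generation.

Mutation is infinite-sites on a fixed lattice of L candidate positions;
recurrent mutation at an occupied site is rejected, which keeps every site
biallelic for the downstream statistics. Internally only currently
segregating columns are stored, so the per-generation cost scales with the
number of segregating sites rather than with L.

The module also houses the two non-genomic fixture generators the rest of
the pipeline is tested against: hemiclone sequencing read counts (for the
phasing stage) and a negative-binomial expression count matrix over the
3-group x 2-temperature x 9-replicate design (for the integration stage).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, HaplotypeMatrix, SampleInfo

INV, STD = 1, 0


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimParams:
    """Wright--Fisher inversion model parameters.

    phi_bp / phi_center define the piecewise gene-flux profile phi(x): sites
    within ``phi_flank`` bp of the nearest breakpoint convert at phi_bp per
    site per generation (in heterokaryotypes), all other sites at phi_center.
    Defaults for the flux rates follow published per-site estimates for
    inversion heterokaryotypes: ~1e-5 in the inversion body and ~1e-7 near
    the breakpoints.
    """

    N: int = 100                      # diploid individuals
    q: float | None = 0.5             # inversion frequency; None = no inversion
    L: int = 2000                     # candidate mutational sites
    chrom_length: int = 1_000_000     # bp
    breakpoints: tuple[int, int] | None = (300_000, 700_000)
    mu: float = 1e-5                  # per site per generation
    r_rate: float = 1e-8              # per bp per generation crossover
    phi_bp: float = 1e-7
    phi_center: float = 1e-5
    phi_flank: int | None = None      # default: 20% of inversion length per side
    s_bal: float = 0.0                # heterokaryotype advantage
    clamp: bool = True                # deterministic restoration of q
    T: int = 200                      # generations
    seed: int = 0
    bottleneck: tuple[int, int, int] | None = None  # (founders, duration, recovery)

    def __post_init__(self) -> None:
        if self.N < 1 or self.T < 1 or self.L < 1:
            raise ValueError("N, T, L must be >= 1")
        if self.q is not None and not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.q is not None and self.breakpoints is None:
            raise ValueError("an inversion needs breakpoints")
        if self.breakpoints is not None:
            b1, b2 = self.breakpoints
            if not (1 <= b1 < b2 <= self.chrom_length):
                raise ValueError("breakpoints must satisfy 1 <= b1 < b2 <= chrom_length")
        for name in ("mu", "r_rate", "phi_bp", "phi_center"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def flank(self) -> int:
        if self.breakpoints is None:
            return 0
        if self.phi_flank is not None:
            return self.phi_flank
        b1, b2 = self.breakpoints
        return (b2 - b1) // 5

    def phi_profile(self, positions: np.ndarray) -> np.ndarray:
        """Per-site conversion rate phi(x) for 1-based bp positions."""
        pos = np.asarray(positions, dtype=np.int64)
        if self.breakpoints is None:
            return np.zeros(pos.shape)
        b1, b2 = self.breakpoints
        d = np.minimum(np.abs(pos - b1), np.abs(pos - b2))
        return np.where(d <= self.flank, self.phi_bp, self.phi_center)


# ---------------------------------------------------------------------------
# Population container
# ---------------------------------------------------------------------------

@dataclass
class SimPopulation:
    """Final-generation population: phased haplotypes plus karyotype labels."""

    haplotypes: HaplotypeMatrix
    karyotypes: np.ndarray            # (2N,) of "INV"/"STD"
    provenance: dict
    # full engine state, needed to derive daughter populations
    _lattice: np.ndarray = field(repr=False, default=None)
    _occupied: np.ndarray = field(repr=False, default=None)
    _col_lat: np.ndarray = field(repr=False, default=None)

    @property
    def positions(self) -> np.ndarray:
        return self.haplotypes.positions

    @property
    def inversion_frequency(self) -> float:
        return float(np.mean(self.karyotypes == "INV"))

    def sample(self, n: int, seed: int, karyotype: str | None = None) -> HaplotypeMatrix:
        """Draw n chromosomes without replacement (optionally one karyotype)."""
        rng = np.random.default_rng(seed)
        idx = np.arange(len(self.karyotypes))
        if karyotype is not None:
            idx = idx[self.karyotypes == karyotype]
        if n > len(idx):
            raise ValueError(f"requested {n} chromosomes, only {len(idx)} available")
        chosen = np.sort(rng.choice(idx, size=n, replace=False))
        return self.haplotypes.take_samples(
            [self.haplotypes.sample_ids[i] for i in chosen])

    def haplotypes_at(self, positions: np.ndarray) -> HaplotypeMatrix:
        """Allele matrix at arbitrary lattice positions.

        Positions that are not currently segregating are reconstructed from
        the mutation ledger: an occupied but non-segregating lattice site
        carries a fixed derived allele (all 1), an unoccupied site is
        ancestral (all 0). Positions off the lattice are rejected.
        """
        positions = np.asarray(positions, dtype=np.int64)
        lat_index = {int(p): i for i, p in enumerate(self._lattice)}
        seg_index = {int(self._lattice[li]): j
                     for j, li in enumerate(self._col_lat)}
        n = len(self.karyotypes)
        out = np.zeros((n, len(positions)), dtype=np.int8)
        for j, p in enumerate(positions):
            li = lat_index.get(int(p))
            if li is None:
                raise KeyError(f"position {p} is not a lattice site")
            if int(p) in seg_index:
                out[:, j] = self.haplotypes.alleles[:, seg_index[int(p)]]
            elif self._occupied[li]:
                out[:, j] = 1
        return HaplotypeMatrix(sample_ids=list(self.haplotypes.sample_ids),
                               chrom=self.haplotypes.chrom,
                               positions=positions, alleles=out)

    def to_sample_info(self, population: str = "sim",
                       continent: str = "sim",
                       latitude_class: str = "NA") -> SampleInfo:
        return SampleInfo(pd.DataFrame({
            "sample_id": self.haplotypes.sample_ids,
            "population": population,
            "continent": continent,
            "karyotype": self.karyotypes,
            "latitude_class": latitude_class,
        }))


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Engine:
    """Mutable simulation state over active (segregating) columns."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.lattice = np.unique(
            np.round(np.linspace(1, params.chrom_length, params.L)).astype(np.int64))
        self.occupied = np.zeros(len(self.lattice), dtype=bool)
        n_chrom = 2 * params.N
        self.G = np.zeros((n_chrom, 0), dtype=np.int8)
        self.col_lat = np.zeros(0, dtype=np.int64)  # lattice index per column
        if params.q is None:
            self.kary = np.zeros(n_chrom, dtype=np.int8)
        else:
            k = int(round(params.q * n_chrom))
            k = min(max(k, 1), n_chrom - 1)
            kary = np.zeros(n_chrom, dtype=np.int8)
            kary[rng.choice(n_chrom, size=k, replace=False)] = INV
            self.kary = kary
        self.inversion_lost = False
        self.lost_generation: int | None = None

    # -- state helpers ------------------------------------------------------

    @property
    def n_chrom(self) -> int:
        return self.G.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return self.lattice[self.col_lat]

    def _cleanup(self) -> None:
        """Drop lost and fixed columns; lost sites become mutable again."""
        if self.G.shape[1] == 0:
            return
        counts = self.G.sum(axis=0, dtype=np.int64)
        lost = counts == 0
        fixed = counts == self.n_chrom
        if lost.any():
            self.occupied[self.col_lat[lost]] = False
        keep = ~(lost | fixed)
        if not keep.all():
            self.G = self.G[:, keep]
            self.col_lat = self.col_lat[keep]

    def _mutate(self, n_chrom: int) -> None:
        lam = n_chrom * len(self.lattice) * self.p.mu
        k = self.rng.poisson(lam)
        if k == 0:
            return
        sites = self.rng.integers(0, len(self.lattice), size=k)
        rows = self.rng.integers(0, n_chrom, size=k)
        new_lat, new_rows = [], []
        for s, r in zip(sites, rows):
            if self.occupied[s]:
                continue  # infinite sites: recurrent mutation rejected
            self.occupied[s] = True
            new_lat.append(s)
            new_rows.append(r)
        if not new_lat:
            return
        cols = np.zeros((n_chrom, len(new_lat)), dtype=np.int8)
        cols[new_rows, np.arange(len(new_lat))] = 1
        col_lat = np.concatenate([self.col_lat, np.array(new_lat, dtype=np.int64)])
        G = np.concatenate([self.G, cols], axis=1)
        order = np.argsort(self.lattice[col_lat], kind="stable")
        self.col_lat = col_lat[order]
        self.G = G[:, order]

    # -- one generation -----------------------------------------------------

    def step(self, size_next: int | None = None) -> None:
        p = self.p
        n_par = self.n_chrom
        n_off = size_next if size_next is not None else n_par
        if n_off % 2:
            raise ValueError("population size must be an even chromosome count")
        rng = self.rng
        n_ind = n_par // 2
        het_par = self.kary[0::2] != self.kary[1::2]  # per parent individual

        neutral = (p.r_rate == 0.0 and p.s_bal == 0.0 and not het_par.any())
        if neutral:
            # fast path: offspring chromosomes are iid draws of parent rows
            rows = rng.integers(0, n_par, size=n_off)
            self.G = self.G[rows]
            self.kary = self.kary[rows]
        else:
            # selection: parent individual drawn with prob proportional to fitness
            if p.s_bal != 0.0:
                w = 1.0 + p.s_bal * het_par
                cdf = np.cumsum(w)
                par = np.searchsorted(cdf, rng.random(n_off) * cdf[-1])
            else:
                par = rng.integers(0, n_ind, size=n_off)
            c0 = rng.integers(0, 2, size=n_off).astype(np.int16)
            off_het = het_par[par]

            # crossover counts: full map for homokaryotypic parents, map
            # excluding the inverted segment for heterokaryotypes
            lam_hom = p.r_rate * (p.chrom_length - 1)
            if p.breakpoints is not None:
                b1, b2 = p.breakpoints
                lam_het = p.r_rate * max(p.chrom_length - 1 - (b2 - b1), 0)
            else:
                b1 = b2 = None
                lam_het = lam_hom
            lam = np.where(off_het, lam_het, lam_hom)
            n_x = rng.poisson(lam) if p.r_rate > 0 else np.zeros(n_off, dtype=int)

            S = self.G.shape[1]
            delta = np.zeros((n_off, S), dtype=np.int16)
            flips_before_mid = np.zeros(n_off, dtype=np.int16)
            mid = (b1 + b2) // 2 if b1 is not None else (p.chrom_length // 2)
            pos = self.positions
            which = np.flatnonzero(n_x > 0)
            for i in which:
                k = n_x[i]
                if off_het[i] and b1 is not None:
                    # uniform over the two collinear segments outside the inversion
                    u = rng.integers(0, p.chrom_length - 1 - (b2 - b1), size=k)
                    x = np.where(u < b1 - 1, u + 1, u + 1 + (b2 - b1))
                else:
                    x = rng.integers(1, p.chrom_length, size=k)
                j = np.searchsorted(pos, x, side="right")
                inside = j < S
                np.add.at(delta[i], j[inside], 1)
                flips_before_mid[i] = np.count_nonzero(x < mid)
            src = (c0[:, None] + np.cumsum(delta, axis=1)) % 2  # 0 -> first chrom
            A = self.G[2 * par]
            B = self.G[2 * par + 1]
            off = np.where(src == 0, A, B).astype(np.int8)
            src_mid = (c0 + flips_before_mid) % 2
            kary_off = np.where(src_mid == 0, self.kary[2 * par],
                                self.kary[2 * par + 1]).astype(np.int8)

            # gene conversion: single-site copy from the homolog in
            # heterokaryotypic parents, rate phi(x) per site per meiosis
            if off_het.any() and S > 0 and (p.phi_bp > 0 or p.phi_center > 0):
                phi = p.phi_profile(pos)
                phi_sum = phi.sum()
                het_idx = np.flatnonzero(off_het)
                n_ev = rng.poisson(len(het_idx) * phi_sum)
                if n_ev > 0:
                    rows_ev = het_idx[rng.integers(0, len(het_idx), size=n_ev)]
                    cols_ev = np.searchsorted(np.cumsum(phi), rng.random(n_ev) * phi_sum)
                    cols_ev = np.minimum(cols_ev, S - 1)
                    donor = np.where(src[rows_ev, cols_ev] == 0,
                                     B[rows_ev, cols_ev], A[rows_ev, cols_ev])
                    off[rows_ev, cols_ev] = donor
            self.G = off
            self.kary = kary_off

        self._mutate(n_off)

        if p.q is not None:
            k_inv = int((self.kary == INV).sum())
            if p.clamp:
                target = int(round(p.q * n_off))
                target = min(max(target, 1), n_off - 1)
                if k_inv == 0 or k_inv == n_off:
                    self.inversion_lost = True
                elif k_inv != target:
                    self._clamp_to(target)
            elif k_inv == 0 or k_inv == n_off:
                self.inversion_lost = True

        self._cleanup()

    def _clamp_to(self, target: int) -> None:
        """Restore karyotype counts by replacing surplus-class chromosomes
        with copies of random chromosomes of the deficit class."""
        rng = self.rng
        inv_idx = np.flatnonzero(self.kary == INV)
        std_idx = np.flatnonzero(self.kary == STD)
        k_inv = len(inv_idx)
        if k_inv > target:
            swap = rng.choice(inv_idx, size=k_inv - target, replace=False)
            src = std_idx[rng.integers(0, len(std_idx), size=len(swap))]
        else:
            swap = rng.choice(std_idx, size=target - k_inv, replace=False)
            src = inv_idx[rng.integers(0, len(inv_idx), size=len(swap))]
        self.G[swap] = self.G[src]
        self.kary[swap] = self.kary[src]

    # -- export -------------------------------------------------------------

    def to_population(self, params: SimParams, generation: int) -> SimPopulation:
        order = np.arange(self.G.shape[1])
        pos = self.positions
        n = self.n_chrom
        ids = [f"hap{i:05d}" for i in range(n)]
        hap = HaplotypeMatrix(
            sample_ids=ids, chrom="sim1",
            positions=pos[order], alleles=self.G[:, order].copy())
        kary = np.where(self.kary == INV, "INV", "STD")
        prov = {
            "params": params,
            "generation": generation,
            "inversion_lost": self.inversion_lost,
        }
        return SimPopulation(haplotypes=hap, karyotypes=kary, provenance=prov,
                             _lattice=self.lattice.copy(),
                             _occupied=self.occupied.copy(),
                             _col_lat=self.col_lat.copy())


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def simulate_inversion_population(params: SimParams) -> SimPopulation:
    """Run the forward model for params.T generations and return the
    final-generation population.

    Loss or fixation of the inversion under drift (possible without the
    clamp) is flagged in ``provenance['inversion_lost']``, never silent.
    """
    rng = np.random.default_rng(params.seed)
    eng = _Engine(params, rng)
    for _ in range(params.T):
        eng.step()
    return eng.to_population(params, params.T)


def simulate_derived_population(pop: SimPopulation, founders: int,
                                generations: int, seed: int,
                                recovery_size: int | None = None,
                                bottleneck_duration: int = 1,
                                founder_karyotype: str | None = None,
                                require_both_karyotypes: bool = False,
                                ) -> SimPopulation:
    """Found a daughter population from ``founders`` chromosomes of ``pop``
    and run it forward; the source population is unchanged.

    The daughter spends ``bottleneck_duration`` generations at the founder
    size, then jumps to ``recovery_size`` chromosomes (default: the source
    size) for the remaining generations. ``founder_karyotype`` restricts the
    founder draw to one class (e.g. an all-standard high-latitude colonist
    pool); the karyotype clamp is disabled in the daughter so its inversion
    frequency drifts freely.
    """
    params: SimParams = pop.provenance["params"]
    n_src = len(pop.karyotypes)
    if founders < 2 or founders % 2:
        raise ValueError("founders must be an even count >= 2")
    if founders > n_src:
        raise ValueError(f"founders ({founders}) exceed source size ({n_src})")
    rng = np.random.default_rng(seed)

    idx = np.arange(n_src)
    if founder_karyotype is not None:
        idx = idx[pop.karyotypes == founder_karyotype]
        if len(idx) == 0:
            raise ValueError(f"karyotype {founder_karyotype!r} absent in source")
        if len(idx) < founders:
            raise ValueError(
                f"only {len(idx)} {founder_karyotype} chromosomes available")
    chosen = rng.choice(idx, size=founders, replace=False)
    if require_both_karyotypes:
        kinds = set(pop.karyotypes[chosen])
        if kinds != {"INV", "STD"}:
            present = set(pop.karyotypes[idx])
            if present != {"INV", "STD"}:
                raise ValueError("both karyotypes requested but source has only "
                                 f"{sorted(present)}")
            # guarantee one of each, keep the draw otherwise random
            inv_pool = idx[pop.karyotypes[idx] == "INV"]
            std_pool = idx[pop.karyotypes[idx] == "STD"]
            chosen[0] = rng.choice(inv_pool)
            chosen[1] = rng.choice(std_pool)

    d_params = replace(params, N=founders // 2, clamp=False, seed=seed,
                       T=max(generations, 1))
    eng = _Engine(d_params, rng)
    eng.lattice = pop._lattice.copy()
    eng.occupied = pop._occupied.copy()
    eng.col_lat = pop._col_lat.copy()
    eng.G = pop.haplotypes.alleles[chosen].copy()
    eng.kary = np.where(pop.karyotypes[chosen] == "INV", INV, STD).astype(np.int8)
    eng._cleanup()  # founder draw may have lost or fixed columns

    recovery = recovery_size if recovery_size is not None else n_src
    if recovery % 2:
        raise ValueError("recovery_size must be an even chromosome count")
    for g in range(generations):
        size_next = founders if g < bottleneck_duration - 1 else recovery
        eng.step(size_next=size_next)
    out = eng.to_population(d_params, generations)
    out.provenance["derived_from"] = pop.provenance.get("generation")
    out.provenance["founders"] = founders
    return out


def merge_populations(pops: dict[str, "SimPopulation"],
                      meta: dict[str, dict] | None = None
                      ) -> tuple[HaplotypeMatrix, SampleInfo]:
    """Combine several populations that share a mutation lattice into one
    matrix over the union of their segregating sites, with per-population
    sample metadata.

    ``meta`` maps population label to extra SampleInfo fields (continent,
    latitude_class). Sample ids are prefixed with the population label.
    """
    labels = sorted(pops)
    union = sorted(set().union(*(set(pops[l].positions.tolist())
                                 for l in labels)))
    union = np.array(union, dtype=np.int64)
    mats, infos = [], []
    for label in labels:
        pop = pops[label]
        m = pop.haplotypes_at(union)
        m.sample_ids = [f"{label}:{s}" for s in m.sample_ids]
        mats.append(m)
        extra = (meta or {}).get(label, {})
        infos.append(pd.DataFrame({
            "sample_id": m.sample_ids,
            "population": label,
            "continent": extra.get("continent", label),
            "karyotype": pop.karyotypes,
            "latitude_class": extra.get("latitude_class", "NA"),
        }))
    combined = HaplotypeMatrix(
        sample_ids=[s for m in mats for s in m.sample_ids],
        chrom=mats[0].chrom, positions=union,
        alleles=np.concatenate([m.alleles for m in mats], axis=0))
    return combined, SampleInfo(pd.concat(infos, ignore_index=True))


# ---------------------------------------------------------------------------
# Hemiclone read-count fixture
# ---------------------------------------------------------------------------

def synth_hemiclone_counts(maternal: HaplotypeMatrix,
                           sire_pool_freqs: np.ndarray,
                           depth_mean: float = 30.0,
                           error_rate: float = 0.001,
                           seed: int = 0,
                           fixed_depth: int | None = None) -> pd.DataFrame:
    """Simulate allele counts for F1 hemiclone libraries.

    Each F1 sample carries one maternal chromosome (a row of ``maternal``)
    over one sire chromosome drawn from a pool with per-site alternate-allele
    frequencies ``sire_pool_freqs``. Per site, sequencing depth is
    Poisson(depth_mean) (or exactly ``fixed_depth``), reads split 50:50
    between the two chromosomes, and each read miscalls with probability
    ``error_rate`` (uniformly to one of the three other bases).

    Returns a tidy table `sample chrom pos A C G T`.
    """
    if depth_mean <= 0 and fixed_depth is None:
        raise ValueError("depth_mean must be > 0")
    freqs = np.asarray(sire_pool_freqs, dtype=float)
    if freqs.shape != (maternal.n_sites,):
        raise ValueError("sire_pool_freqs must have one entry per site")
    rng = np.random.default_rng(seed)
    bases = np.array(["A", "C", "G", "T"])
    base_idx = {b: i for i, b in enumerate(bases)}

    ref_idx = np.array([base_idx[b] for b in maternal.ref])
    alt_idx = np.array([base_idx[b] for b in maternal.alt])

    records = []
    n_sites = maternal.n_sites
    for si, sample in enumerate(maternal.sample_ids):
        sire_allele = (rng.random(n_sites) < freqs).astype(np.int8)
        mat_allele = maternal.alleles[si]
        if fixed_depth is not None:
            depth = np.full(n_sites, int(fixed_depth))
        else:
            depth = rng.poisson(depth_mean, size=n_sites)
        mat_reads = rng.binomial(depth, 0.5)
        counts = np.zeros((n_sites, 4), dtype=np.int64)
        for j in range(n_sites):
            if mat_allele[j] == MISSING:
                continue
            m_base = alt_idx[j] if mat_allele[j] == 1 else ref_idx[j]
            s_base = alt_idx[j] if sire_allele[j] == 1 else ref_idx[j]
            reads = np.full(depth[j], s_base)
            reads[: mat_reads[j]] = m_base
            if error_rate > 0 and depth[j] > 0:
                err = rng.random(depth[j]) < error_rate
                if err.any():
                    shift = rng.integers(1, 4, size=int(err.sum()))
                    reads[err] = (reads[err] + shift) % 4
            counts[j] = np.bincount(reads, minlength=4)
        for j in range(n_sites):
            records.append((sample, maternal.chrom, int(maternal.positions[j]),
                            *counts[j]))
    return pd.DataFrame.from_records(
        records, columns=["sample", "chrom", "pos", "A", "C", "G", "T"])


def synth_pool_counts(maternal: HaplotypeMatrix,
                      sire_pool_freqs: np.ndarray,
                      depth: int = 200, seed: int = 0) -> pd.DataFrame:
    """Allele counts for the pooled-sire reference library (near-monomorphic
    pools mimic an isogenic sire stock; intermediate freqs create the
    pool-polymorphic sites the phasing filters must reject)."""
    freqs = np.asarray(sire_pool_freqs, dtype=float)
    rng = np.random.default_rng(seed)
    bases = ["A", "C", "G", "T"]
    base_idx = {b: i for i, b in enumerate(bases)}
    records = []
    for j in range(maternal.n_sites):
        counts = np.zeros(4, dtype=np.int64)
        k_alt = rng.binomial(depth, freqs[j])
        counts[base_idx[maternal.alt[j]]] += k_alt
        counts[base_idx[maternal.ref[j]]] += depth - k_alt
        records.append((maternal.chrom, int(maternal.positions[j]), *counts))
    return pd.DataFrame.from_records(
        records, columns=["chrom", "pos", "A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Expression-design fixture
# ---------------------------------------------------------------------------

GROUPS = ("FI", "FS", "MS")
TEMPERATURES = (18, 25)
N_REPLICATES = 9


@dataclass(frozen=True)
class ExpressionEffect:
    """Per-gene log2 fold changes over the factorial design.

    karyotype_lfc applies to the inverted group (FI), geography_lfc to the
    high-latitude group (MS), temperature_lfc to 18 C, and interaction_lfc
    to FI at 18 C only.
    """

    gene_id: str
    karyotype_lfc: float = 0.0
    geography_lfc: float = 0.0
    temperature_lfc: float = 0.0
    interaction_lfc: float = 0.0


def synth_expression_design(n_genes: int,
                            effect_spec: Sequence[ExpressionEffect] = (),
                            seed: int = 0,
                            base_mean: float = 200.0,
                            dispersion: float = 0.1,
                            lib_size_cv: float = 0.15,
                            inversion_span: tuple[int, int] = (16_432_209, 24_744_010),
                            chrom_length: int = 32_000_000,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts over the full 3x2x9 factorial design.

    Returns (counts genes x samples, design table, gene table). The design
    table enumerates exactly the full factorial of three groups (FI, FS, MS)
    by two temperatures by nine replicates = 54 samples. Genes are placed
    uniformly on a pseudo-chromosome and tagged inside/outside the declared
    inversion interval.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    effects = {e.gene_id: e for e in effect_spec}
    unknown = set(effects) - set(gene_ids)
    if unknown:
        raise ValueError(f"effect_spec names unknown genes: {sorted(unknown)}")

    design = pd.DataFrame(
        [(f"{g}_{t}_{r + 1}", g, t, r + 1)
         for g, t, r in itertools.product(GROUPS, TEMPERATURES,
                                          range(N_REPLICATES))],
        columns=["sample_id", "group", "temperature", "replicate"])

    starts = np.sort(rng.integers(1, chrom_length - 5000, size=n_genes))
    gene_table = pd.DataFrame({
        "gene_id": gene_ids,
        "chrom": "3R",
        "start": starts,
        "end": starts + 2000,
    })
    mid = (gene_table["start"] + gene_table["end"]) // 2
    gene_table["inside_inversion"] = (
        (mid >= inversion_span[0]) & (mid <= inversion_span[1]))
    for col in ("karyotype_lfc", "geography_lfc", "temperature_lfc",
                "interaction_lfc"):
        gene_table[col] = [getattr(effects.get(g, None), col, 0.0)
                           if g in effects else 0.0 for g in gene_ids]

    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    lib_factor = rng.lognormal(mean=0.0, sigma=lib_size_cv,
                               size=len(design))

    counts = np.zeros((n_genes, len(design)), dtype=np.int64)
    is_fi = (design["group"] == "FI").to_numpy()
    is_ms = (design["group"] == "MS").to_numpy()
    is_18 = (design["temperature"] == 18).to_numpy()
    lfc = (np.outer(gene_table["karyotype_lfc"], is_fi)
           + np.outer(gene_table["geography_lfc"], is_ms)
           + np.outer(gene_table["temperature_lfc"], is_18)
           + np.outer(gene_table["interaction_lfc"], is_fi & is_18))
    mean = base[:, None] * (2.0 ** lfc) * lib_factor[None, :]
    # NB parameterised by mean m and dispersion a: var = m + a m^2
    if dispersion > 0:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=gene_ids,
                             columns=design["sample_id"])
    counts_df.index.name = "gene_id"
    return counts_df, design, gene_table
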