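"""Readers/writers for the standard formats the pipeline touches.

This module is the single authority for coordinate conventions: internal
coordinates are 1-based inclusive everywhere (matching the printed cytological
coordinates the analyses are anchored on, e.g. 3R:16,432,209); BED is the only
0-based, half-open surface and conversion happens exactly once, here.

Haplotype data are held as a dense biallelic matrix of haploid allele codes
(0 = reference-class allele, 1 = alternate, -1 = missing) because every
downstream statistic (pi, Tajima's D, r2, F_ST/F_AT) consumes per-site sample
configurations, not genotype likelihoods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

KARYOTYPES = ("INV", "STD", "HET", "UNKNOWN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes: ``alleles[i, j]`` is sample i at site j.

    positions are 1-based bp, strictly increasing; alleles are int8 with
    0 (ref-class), 1 (alt) and -1 (missing, never silently imputed).
    """

    sample_ids: list[str]
    chrom: str
    positions: np.ndarray  # (S,) int64, 1-based, strictly increasing
    alleles: np.ndarray    # (n_samples, S) int8 in {0, 1, -1}
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (samples x sites)")
        if self.alleles.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.positions)} sites"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1 or -1 (missing)")
        if not self.ref:
            self.ref = ["A"] * self.n_sites
        if not self.alt:
            self.alt = ["T"] * self.n_sites

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def take_samples(self, ids: Sequence[str]) -> "HaplotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        rows = [index[s] for s in ids]
        return HaplotypeMatrix(
            sample_ids=list(ids), chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles[rows].copy(),
            ref=list(self.ref), alt=list(self.alt),
        )

    def take_sites(self, site_idx: np.ndarray) -> "HaplotypeMatrix":
        site_idx = np.asarray(site_idx)
        if site_idx.dtype == bool:
            site_idx = np.flatnonzero(site_idx)
        return HaplotypeMatrix(
            sample_ids=list(self.sample_ids), chrom=self.chrom,
            positions=self.positions[site_idx],
            alleles=self.alleles[:, site_idx].copy(),
            ref=[self.ref[i] for i in site_idx],
            alt=[self.alt[i] for i in site_idx],
        )

    def region_mask(self, start: int, end: int) -> np.ndarray:
        """Boolean site mask for 1-based inclusive span [start, end]."""
        return (self.positions >= start) & (self.positions <= end)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (count of allele 1, count of non-missing)."""
        a = self.alleles
        n = (a != MISSING).sum(axis=0)
        c1 = (a == 1).sum(axis=0)
        return c1, n


@dataclass
class SampleInfo:
    """Per-sample metadata: population, continent, karyotype, latitude class."""

    table: pd.DataFrame  # columns: sample_id population continent karyotype latitude_class

    REQUIRED = ("sample_id", "population", "continent", "karyotype")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"SampleInfo missing column {col!r}")
        if "latitude_class" not in self.table.columns:
            self.table = self.table.assign(latitude_class="NA")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in SampleInfo")
        bad = set(self.table["karyotype"]) - set(KARYOTYPES)
        if bad:
            raise ValueError(f"unknown karyotype labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SampleInfo":
        return cls(pd.DataFrame.from_records(list(records)))

    @classmethod
    def read_tsv(cls, path) -> "SampleInfo":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def ids(self, **filters) -> list[str]:
        """Sample ids matching equality filters, e.g. population='Florida'."""
        t = self.table
        for col, val in filters.items():
            t = t[t[col] == val]
        return list(t["sample_id"])

    def karyotype_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["karyotype"].iloc[0]


class MaskTrack:
    """Per-position pass(1)/fail(0) flags over a declared 1-based interval.

    Stored internally as a sorted set of pass intervals (1-based inclusive);
    positions inside the declared span but outside any interval are fail.
    """

    def __init__(self, chrom: str, span: tuple[int, int],
                 pass_intervals: Iterable[tuple[int, int]] = ()):
        self.chrom = chrom
        self.span = (int(span[0]), int(span[1]))
        ivs = sorted((int(a), int(b)) for a, b in pass_intervals)
        for a, b in ivs:
            if a > b:
                raise ValueError(f"bad interval {(a, b)}")
        # merge overlapping / adjacent
        merged: list[list[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        self.intervals: list[tuple[int, int]] = [tuple(m) for m in merged]
        self._starts = np.array([a for a, _ in self.intervals], dtype=np.int64)
        self._ends = np.array([b for _, b in self.intervals], dtype=np.int64)

    @classmethod
    def all_pass(cls, chrom: str, span: tuple[int, int]) -> "MaskTrack":
        return cls(chrom, span, [span])

    def passes(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised flag lookup for 1-based positions."""
        pos = np.asarray(positions, dtype=np.int64)
        if len(self._starts) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self._starts, pos, side="right") - 1
        ok = idx >= 0
        res = np.zeros(pos.shape, dtype=bool)
        res[ok] = pos[ok] <= self._ends[idx[ok]]
        return res

    def n_pass_in(self, start: int, end: int) -> int:
        """Count of pass positions within 1-based inclusive [start, end]."""
        total = 0
        for a, b in self.intervals:
            lo, hi = max(a, start), min(b, end)
            if lo <= hi:
                total += hi - lo + 1
        return total

    def __eq__(self, other) -> bool:
        return (isinstance(other, MaskTrack) and self.chrom == other.chrom
                and self.intervals == other.intervals)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: malformed strand {self.strand!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region: str | None = None,
             multiallelic_major_fraction: float = 0.95) -> HaplotypeMatrix:
    """Read phased haplotypes from a VCF into a biallelic matrix.

    Haploid GT ("0"/"1") is taken as-is; homozygous diploid GT collapses to
    the shared allele; heterozygous diploid GT becomes missing for that
    sample (ambiguous phase is excluded rather than guessed). Multiallelic
    records keep the two most frequent alleles when those cover at least
    ``multiallelic_major_fraction`` of non-missing calls, else the site is
    dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    chrom: str | None = None

    # region filtering is done here rather than via an index query so that
    # plain-text (untabixed) VCFs work identically
    r_chrom, r_lo, r_hi = None, None, None
    if region:
        if ":" in region:
            r_chrom, span = region.split(":", 1)
            lo, hi = span.replace(",", "").split("-")
            r_lo, r_hi = int(lo), int(hi)
        else:
            r_chrom = region

    for var in vcf:
        if r_chrom is not None:
            if var.CHROM != r_chrom:
                continue
            if r_lo is not None and not (r_lo <= var.POS <= r_hi):
                continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise ValueError(
                f"mixed chromosomes in query: {chrom} vs {var.CHROM}; "
                "use region= to restrict"
            )
        gts = var.genotypes  # list of [a, (b,), phased]
        calls = np.full(len(samples), MISSING, dtype=np.int8)
        raw = []
        for i, g in enumerate(gts):
            alleles = [a for a in g[:-1] if a is not None and a >= 0]
            if not alleles:
                raw.append(None)
            elif len(set(alleles)) == 1:
                raw.append(alleles[0])
            else:  # heterozygous diploid -> missing
                raw.append(None)
        alt_list = list(var.ALT)
        all_alleles = [var.REF] + alt_list
        if len(alt_list) > 1:
            obs = [a for a in raw if a is not None]
            if not obs:
                continue
            counts = np.bincount(obs, minlength=len(all_alleles))
            order = np.argsort(counts)[::-1]
            top2 = sorted(order[:2].tolist())
            if counts[top2].sum() < multiallelic_major_fraction * counts.sum():
                continue  # no dominant biallelic configuration; drop site
            code = {top2[0]: 0, top2[1]: 1}
            ref_base = all_alleles[top2[0]]
            alt_base = all_alleles[top2[1]]
            for i, a in enumerate(raw):
                if a in code:
                    calls[i] = code[a]
        else:
            ref_base = var.REF
            alt_base = alt_list[0] if alt_list else "."
            for i, a in enumerate(raw):
                if a is not None:
                    if a > 1:
                        raise ValueError(
                            f"allele index {a} without ALT at {var.CHROM}:{var.POS}")
                    calls[i] = a
        positions.append(var.POS)
        refs.append(ref_base)
        alts.append(alt_base)
        rows.append(calls)

    if chrom is None:
        raise ValueError(f"no records read from {path} (region={region!r})")
    alleles = (np.stack(rows, axis=1) if rows
               else np.zeros((len(samples), 0), dtype=np.int8))
    return HaplotypeMatrix(sample_ids=samples, chrom=chrom,
                           positions=np.array(positions, dtype=np.int64),
                           alleles=alleles, ref=refs, alt=alts)


def write_vcf(matrix: HaplotypeMatrix, path,
              contig_length: int | None = None) -> None:
    """Write a HaplotypeMatrix as VCF 4.2 with haploid GT fields."""
    length = int(contig_length or (matrix.positions.max() if matrix.n_sites else 1))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j in range(matrix.n_sites):
            gts = ["." if a == MISSING else str(int(a))
                   for a in matrix.alleles[:, j]]
            fh.write(f"{matrix.chrom}\t{matrix.positions[j]}\t.\t"
                     f"{matrix.ref[j]}\t{matrix.alt[j]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------

def read_mask_bed(path, chrom: str | None = None,
                  span: tuple[int, int] | None = None) -> MaskTrack:
    """Read pass intervals from BED (0-based half-open) into a MaskTrack.

    Policy for an empty BED: with a declared chrom and span the track
    defaults to all-pass (no mask evidence means no exclusions); without a
    declared span an error is raised, as there is nothing to anchor the
    track on.
    """
    intervals: list[tuple[int, int]] = []
    seen_chrom = chrom
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            c, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if seen_chrom is None:
                seen_chrom = c
            if c != seen_chrom:
                continue
            # BED 0-based half-open -> 1-based inclusive
            intervals.append((start0 + 1, end0))
    if seen_chrom is None and span is None:
        raise ValueError(f"empty BED {path} and no chrom/span declared")
    if not intervals:
        if span is None:
            raise ValueError(f"no intervals for {seen_chrom} in {path}")
        return MaskTrack.all_pass(seen_chrom or "NA", span)
    if span is None:
        span = (min(a for a, _ in intervals), max(b for _, b in intervals))
    return MaskTrack(seen_chrom, span, intervals)


def write_mask_bed(track: MaskTrack, path) -> None:
    """Write pass intervals as BED (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for a, b in track.intervals:
            fh.write(f"{track.chrom}\t{a - 1}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene models and GO map
# ---------------------------------------------------------------------------

_GFF_ATTR = re.compile(r"(?:^|;)\s*(ID|gene_id|Name)=([^;]+)")


def read_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3 (type == gene) or a 4+ column TSV.

    TSV columns: gene_id chrom start end [strand]; GFF3 spans are already
    1-based inclusive and are taken as-is.
    """
    genes: list[GeneModel] = []
    path = Path(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 8 and parts[2]:  # GFF3
                if parts[2] != "gene":
                    continue
                m = _GFF_ATTR.search(parts[8] if len(parts) > 8 else "")
                gid = m.group(2) if m else f"gene_{ln}"
                genes.append(GeneModel(gid, parts[0], int(parts[3]),
                                       int(parts[4]), parts[6]))
            else:  # TSV
                gid, chrom, start, end = parts[:4]
                strand = parts[4] if len(parts) > 4 else "+"
                genes.append(GeneModel(gid, chrom, int(start), int(end), strand))
    return genes


def read_go_map(path) -> dict[str, set[str]]:
    """gene -> set of GO ids from TSV `gene_id<TAB>GO:xxx[,GO:yyy...]`."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, terms = line.split("\t")[:2]
            out.setdefault(gene, set()).update(
                t.strip() for t in terms.split(",") if t.strip())
    return out


def write_go_map(go_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            fh.write(f"{gene}\t{','.join(sorted(go_map[gene]))}\n")


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def write_nexus(matrix: HaplotypeMatrix, path,
                max_missing_rate: float = 0.5) -> None:
    """Write a binary CHARACTERS matrix loadable by split-network software.

    datatype=standard with symbols "01" and missing "?"; taxa with spaces
    are quoted. Refuses samples whose missing fraction exceeds
    ``max_missing_rate`` (networks on mostly-absent taxa mislead).
    """
    if len(set(matrix.sample_ids)) != matrix.n_samples:
        raise ValueError("duplicate taxon labels")
    if matrix.n_sites:
        miss = (matrix.alleles == MISSING).mean(axis=1)
        over = [s for s, m in zip(matrix.sample_ids, miss) if m > max_missing_rate]
        if over:
            raise ValueError(
                f"samples exceed missing-rate {max_missing_rate}: {over}")

    def label(s: str) -> str:
        return f"'{s}'" if re.search(r"\s", s) else s

    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={matrix.n_samples};\n")
        fh.write("    TAXLABELS\n")
        for s in matrix.sample_ids:
            fh.write(f"        {label(s)}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write(f"    DIMENSIONS NCHAR={matrix.n_sites};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        fh.write("    MATRIX\n")
        for i, s in enumerate(matrix.sample_ids):
            row = "".join("?" if a == MISSING else str(int(a))
                          for a in matrix.alleles[i])
            fh.write(f"        {label(s)} {row}\n")
        fh.write("    ;\nEND;\n")


def read_nexus(path) -> HaplotypeMatrix:
    """Re-parse a NEXUS file written by :func:`write_nexus` (round-trip aid)."""
    taxa: list[str] = []
    rows: list[str] = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.upper() == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if s == ";":
                    in_matrix = False
                    continue
                if not s:
                    continue
                m = re.match(r"^(?:'([^']+)'|(\S+))\s+([01?]+)$", s)
                if not m:
                    raise ValueError(f"unparseable matrix line: {s!r}")
                taxa.append(m.group(1) or m.group(2))
                rows.append(m.group(3))
    if not rows:
        raise ValueError(f"no MATRIX block in {path}")
    code = {"0": 0, "1": 1, "?": MISSING}
    alleles = np.array([[code[c] for c in r] for r in rows], dtype=np.int8)
    positions = np.arange(1, alleles.shape[1] + 1, dtype=np.int64)
    return HaplotypeMatrix(sample_ids=taxa, chrom="nexus",
                           positions=positions, alleles=alleles)
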