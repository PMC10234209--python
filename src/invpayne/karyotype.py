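"""Diagnostic marker panels and karyotype classification.

A marker panel is a set of SNPs that are strongly diagnostic of inversion
status (near-fixed differences between known inverted and standard
chromosomes). Classification counts, per sample, the fraction of informative
panel markers carrying the inversion-associated allele; near-unanimous
samples are called INV or STD, intermediate samples HET, and samples with
too few informative markers UNKNOWN. Heterokaryotypic and unknown samples
are excluded from downstream karyotype-resolved analyses by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, HaplotypeMatrix, SampleInfo
from .differentiation import fst_series


@dataclass
class MarkerPanel:
    """(chrom, pos, inversion allele code, standard allele code) per marker."""

    table: pd.DataFrame  # columns: chrom pos inv_allele std_allele
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"chrom", "pos", "inv_allele", "std_allele"}
        if not req <= set(self.table.columns):
            raise ValueError(f"panel table needs columns {sorted(req)}")
        if self.table["pos"].duplicated().any():
            raise ValueError("duplicate marker positions")
        if (self.table["inv_allele"] == self.table["std_allele"]).any():
            raise ValueError("markers must have distinct alleles per class")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path) -> "MarkerPanel":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def derive_marker_panel(matrix: HaplotypeMatrix, samples: SampleInfo,
                        fst_min: float = 0.9, freq_min: float = 0.95
                        ) -> MarkerPanel:
    """Derive diagnostic markers from a training set with known karyotypes.

    A site qualifies when between-class F_AT >= fst_min, the inversion
    allele frequency is >= freq_min among INV and <= 1 - freq_min among STD
    training chromosomes.
    """
    inv_ids = [s for s in samples.ids(karyotype="INV") if s in matrix.sample_ids]
    std_ids = [s for s in samples.ids(karyotype="STD") if s in matrix.sample_ids]
    if len(inv_ids) < 2 or len(std_ids) < 2:
        raise ValueError("need >= 2 training samples per karyotype class")
    theta = fst_series(matrix, inv_ids, std_ids).to_numpy()
    inv = matrix.take_samples(inv_ids).alleles
    std = matrix.take_samples(std_ids).alleles
    with np.errstate(invalid="ignore", divide="ignore"):
        f_inv = (inv == 1).sum(axis=0) / (inv != MISSING).sum(axis=0)
        f_std = (std == 1).sum(axis=0) / (std != MISSING).sum(axis=0)
    # orient: the inversion allele is whichever allele is the majority in INV
    inv_allele = np.where(f_inv >= 0.5, 1, 0)
    f_inv_orient = np.where(inv_allele == 1, f_inv, 1 - f_inv)
    f_std_orient = np.where(inv_allele == 1, f_std, 1 - f_std)
    ok = ((theta >= fst_min)
          & (f_inv_orient >= freq_min)
          & (f_std_orient <= 1 - freq_min))
    ok &= ~np.isnan(theta)
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        warnings.warn("no qualifying diagnostic sites; empty panel")
    table = pd.DataFrame({
        "chrom": matrix.chrom,
        "pos": matrix.positions[idx],
        "inv_allele": inv_allele[idx],
        "std_allele": 1 - inv_allele[idx],
    })
    prov = {"n_inv_training": len(inv_ids), "n_std_training": len(std_ids),
            "fst_min": fst_min, "freq_min": freq_min}
    return MarkerPanel(table, prov)


def classify_karyotypes(matrix: HaplotypeMatrix, panel: MarkerPanel,
                        min_markers: int = 2, call_threshold: float = 0.9,
                        population: str = "NA", continent: str = "NA"
                        ) -> SampleInfo:
    """Call INV/STD/HET/UNKNOWN per sample from panel markers.

    f = fraction of informative (non-missing) panel markers carrying the
    inversion allele; f >= call_threshold -> INV, f <= 1 - call_threshold ->
    STD, otherwise HET. Fewer than min_markers informative markers ->
    UNKNOWN.
    """
    if len(panel) == 0:
        raise ValueError("marker panel is empty")
    pos_index = {int(p): j for j, p in enumerate(matrix.positions)}
    cols, inv_alleles = [], []
    for _, row in panel.table.iterrows():
        j = pos_index.get(int(row["pos"]))
        if j is not None:
            cols.append(j)
            inv_alleles.append(int(row["inv_allele"]))
    calls = []
    for i, sample in enumerate(matrix.sample_ids):
        hits = informative = 0
        for j, inv_a in zip(cols, inv_alleles):
            a = matrix.alleles[i, j]
            if a == MISSING:
                continue
            informative += 1
            hits += int(a == inv_a)
        if informative < min_markers:
            kary = "UNKNOWN"
        else:
            f = hits / informative
            if f >= call_threshold:
                kary = "INV"
            elif f <= 1 - call_threshold:
                kary = "STD"
            else:
                kary = "HET"
        calls.append({"sample_id": sample, "population": population,
                      "continent": continent, "karyotype": kary,
                      "latitude_class": "NA"})
    return SampleInfo(pd.DataFrame(calls))
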