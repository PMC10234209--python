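# invpayne

Karyotype-resolved population genomics of a balanced chromosomal inversion
polymorphism.

Large polymorphic inversions such as the cosmopolitan 3R arrangement of
*Drosophila melanogaster* suppress recombination in heterokaryotypes,
partition a population's chromosomes into two long-lived allelic classes,
and — when held at intermediate frequency by balancing selection — leave a
characteristic set of genomic signatures: monophyletic clustering of
inverted chromosomes, a "suspension-bridge" profile of between-karyotype
differentiation (F_AT) peaking at the breakpoints and in the inversion
center, reduced nucleotide diversity at the breakpoints, long-range linkage
disequilibrium in pooled samples, and sharing of inversion-associated
alleles across continents. `invpayne` implements the full analysis chain
used to detect and quantify these signatures, together with a forward
Wright–Fisher simulator of the inversion polymorphism that generates the
test data for every stage, so the pipeline is verifiable end-to-end without
any external download.

The package is aimed at population geneticists who work with phased,
karyotyped haplotypes (single-individual or hemiclone sequencing designs)
and want the inversion-specific analyses as tested, scriptable library
functions rather than one-off scripts.

## What is inside

| stage | module | core quantities |
|---|---|---|
| forward simulation | `invpayne.simulate` | Wright–Fisher engine with karyotype-dependent crossover, position-dependent gene flux Φ(x), balancing selection; bottleneck-derived populations; hemiclone and RNA-seq fixtures |
| file formats | `invpayne.io_formats` | VCF (haploid GT), BED masks, GFF3/TSV genes, GO maps, NEXUS export (1-based inclusive coordinates everywhere; BED is the only 0-based surface) |
| phasing | `invpayne.phasing` | maternal-haplotype reconstruction from F1 counts: pool homozygosity (<10% MAF), summed wild-allele count ≥ 10, exact central 90% binomial interval at p = 0.5, coverage ≥ 15 and ≤ 95th percentile |
| karyotyping | `invpayne.karyotype` | diagnostic marker panels (F_AT ≥ 0.9), INV/STD/HET/UNKNOWN calls |
| diversity | `invpayne.diversity` | per-site π, Tajima's D, quality masks (>50% rule), masked 100-kb windows, inside/outside-inversion partition |
| LD | `invpayne.ld` | r², SNP–inversion LD, seeded SNP subsampling, expected-r² decay fit E(r²) = [(10+C)/((2+C)(11+C))]·[1+((3+C)(12+12C+C²))/(n(2+C)(11+C))] with nested-model F test |
| differentiation | `invpayne.differentiation` | per-SNP haploid Weir–Cockerham θ, K / G / G+K comparison plans, windowed averages, K_ST, cross-continent inverted-chromosome F_ST, one-way ANOVA + Tukey HSD |
| candidates | `invpayne.candidates` | F_AT ≥ 0.9 candidate SNPs, ±2-kb gene mapping, exact multi-set intersection test, SNP-permutation GO enrichment, SNP-class Fisher tests, inversion-specific allele profiling |
| integration | `invpayne.integrate` | CPM/TMM normalisation, low-expression filter, F_AT-based gene ranking, rank–rank hypergeometric overlap (RRHO), region-enrichment Fisher tests |
| networks | `invpayne.network` | Jukes–Cantor distances, NEXUS for split-network software, karyotype-vs-geography clustering permutation test |

See `docs/methods.md` for the model, estimators and validation design.

## Worked example

Simulate a balanced inversion, derive a marker panel on half the
chromosomes, classify the other half, and measure between-karyotype
differentiation inside vs outside the breakpoints:

```python
import numpy as np
from invpayne import (SimParams, simulate_inversion_population, SampleInfo,
                      derive_marker_panel, classify_karyotypes, fst_series)

params = SimParams(N=100, q=0.5, L=2000, chrom_length=1_000_000,
                   breakpoints=(250_000, 750_000), mu=5e-5, r_rate=5e-7,
                   phi_bp=1e-7, phi_center=1e-5, clamp=True, T=1200, seed=0)
pop = simulate_inversion_population(params)

ids = pop.haplotypes.sample_ids
train, test = ids[0::2], ids[1::2]
info = pop.to_sample_info()
panel = derive_marker_panel(
    pop.haplotypes.take_samples(train),
    SampleInfo(info.table[info.table.sample_id.isin(train)]))
calls = classify_karyotypes(pop.haplotypes.take_samples(test), panel)

truth = dict(zip(ids, pop.karyotypes))
acc = np.mean([calls.karyotype_of(s) == truth[s] for s in test])

inv = [s for s, k in truth.items() if k == "INV"]
std = [s for s, k in truth.items() if k == "STD"]
theta = fst_series(pop.haplotypes, inv, std)
inside = (theta.index >= 250_000) & (theta.index <= 750_000)
print(f"panel size      : {len(panel)}")
print(f"accuracy        : {acc:.3f}")
print(f"mean F_AT inside : {np.nanmean(theta[inside]):.3f}")
print(f"mean F_AT outside: {np.nanmean(theta[~inside]):.3f}")
```

Output:

```
panel size      : 97
accuracy        : 1.000
mean F_AT inside : 0.615
mean F_AT outside: 0.059
```

The panel's 97 diagnostic SNPs classify every held-out chromosome
correctly, and differentiation between the karyotype classes is an order of
magnitude higher inside the inverted region than outside it — the
recombination-suppression signal the downstream candidate-calling stage
thresholds on.

A thin CLI mirrors the main stages
(`invpayne simulate|convert|phase|karyotype|diversity|fst|ld|network`);
run `invpayne --help`.

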