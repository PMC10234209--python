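# Methods

`invpayne` re-implements, as a tested pipeline, the karyotype-resolved
population-genomic and integrative analyses used to characterise a large
cosmopolitan chromosomal inversion segregating as a balanced polymorphism:
bioinformatic phasing of wild chromosomes, marker-based karyotyping,
windowed diversity and Tajima's D, linkage disequilibrium and its decay,
Weir–Cockerham differentiation between karyotypes and populations,
candidate-SNP/gene calling with enrichment tests, and the overlap between
genomic and transcriptomic candidates. Every stage is driven and tested by
a forward simulator of the inversion polymorphism, so the whole pipeline is
exercised end-to-end without any external data.

## The forward model

A single panmictic Wright–Fisher population of `N` diploids (2N
chromosomes) evolves on one linear chromosome. The inversion is a
per-chromosome label, not a sequence rearrangement: every statistic in the
pipeline is computed in reference coordinates, so the model only needs the
inversion's three population-genetic consequences:

* **Recombination suppression.** Crossovers occur at `r_rate` per bp per
  meiosis. In heterokaryotypic parents, crossover positions are restricted
  to the region outside the breakpoints (single crossovers inside an
  inversion loop produce inviable aneuploid gametes); homokaryotypic
  parents recombine freely.
* **Gene flux.** In heterokaryotypes, single sites are copied between the
  karyotype backgrounds at a per-site, per-generation rate `phi(x)` —
  a piecewise profile equal to `phi_bp` within `phi_flank` bp of the
  nearest breakpoint and `phi_center` elsewhere. Per-site (not
  tract-based) conversion is used because per-site flux is the quantity
  with published estimates (\~1e-5 in the inversion body, \~1e-7 near the
  breakpoints for heterokaryotypes); those are the defaults.
* **Balancing selection.** Either a symmetric heterokaryotype fitness
  advantage `1 + s_bal`, or a deterministic "clamp" that restores the
  karyotype counts to the target frequency `q` each generation (the
  clamp models *maintained frequency* without committing to a mechanism,
  which is what the theory being reproduced assumes). Loss or fixation of
  the inversion under drift is flagged in the provenance, never silent.

Mutation is infinite-sites on a lattice of `L` candidate positions;
recurrent mutation at an occupied site is rejected, keeping all sites
biallelic. Internally only segregating columns are stored (with the
occupied/ancestral ledger retained so monomorphic states can be
reconstructed), which makes the per-generation cost proportional to the
number of segregating sites.

**Scaling.** Desk-scale runs use 2N = 100–400 chromosomes and a 1-Mb
chromosome. What the statistics respond to are the population-scaled
products (4Nμ, 4Nr, 4NΦ), so test fixtures preserve those products rather
than the raw per-site rates: e.g. a biologically realistic central flux of
1e-5/site/generation at Ne ≈ 1e6 corresponds to \~0.05/site/generation at
2N = 200. Fixture parameter sets in the test suite state which regime they
emulate (flux-differentiated for the suspension-bridge pattern;
near-suppressed flux for marker-panel, clustering and LD contrasts).

**Derived populations** are founded from a seeded draw of founder
chromosomes (optionally restricted to one karyotype, emulating the
colonisation of high latitudes by standard chromosomes), spend a declared
number of generations at the founder size, then recover to a target size.
The karyotype clamp is disabled in daughters; polymorphic daughters keep
the heterokaryotype advantage so the balanced polymorphism persists
through the bottleneck, as it must for the scenario being modelled.

## Fixture generators

* `synth_hemiclone_counts` emulates the F1 hemiclone sequencing design:
  each F1 library carries one maternal wild chromosome over one sire
  chromosome drawn from a pooled reference; per site, depth is
  Poisson-distributed, reads split 50:50 between the two chromosomes and
  miscall at a given error rate. It does **not** model mapping bias,
  indels, base-quality structure or duplicate reads — passing phasing
  tests demonstrate the filter cascade's logic, not robustness to
  alignment artefacts.
* `synth_expression_design` produces negative-binomial counts over the
  full factorial of three groups (low-latitude inverted FI, low-latitude
  standard FS, high-latitude standard MS) × two developmental temperatures
  (18/25 °C) × nine replicates = 54 samples, with per-gene log2
  fold-changes for karyotype, geography, temperature and the
  karyotype-at-cold interaction. Library sizes are log-normal;
  gene-specific dispersion is constant (default 0.1). It does not model
  batch structure or line random effects.

## Statistics

* **π and Tajima's D** are computed from per-site sample allele
  configurations; windowed averages divide by the number of mask-pass
  positions in each 100-kb window (anchored at position 1, final partial
  window kept), so positions failing quality criteria (>50% of samples
  failing, strictly) never enter the denominator. Sites with missing calls
  use the non-missing subset; the D constants use the modal sample size
  and sites below 0.8× the modal n are dropped.
* **Weir–Cockerham θ** is the haploid variance-components estimator
  (MSP/MSG/n_c form) — the data are phased chromosomes, so there is no
  within-individual component. Window summaries are unweighted means of
  defined per-SNP θ with negative estimates retained. Between karyotype
  classes the same quantity is called F_AT; karyotype pools are equal-size
  (50:50) by default with seeded subsampling. K_ST (1 − K_S/K_T with
  sample-size-weighted K_S) with a label-permutation p-value is provided
  as the companion test.
* **LD.** r² is the squared allele-frequency correlation on complete-case
  haplotypes, with a MAF ≥ 0.1 filter applied within the analysed group.
  The decay fit minimises least squares of observed r² against the classic
  drift-sampling expectation E(r²|C, n) with C = ρ·distance; the pooled
  (one ρ) and per-karyotype (ρ per group) models are compared by an
  extra-sum-of-squares F test. ρ is optimised in log space from a coarse
  grid, bounded away from negative values; a boundary estimate is flagged.
  Note the expectation floors at 1/n for finite samples — the curve does
  not approach zero at large distance.
* **Multi-set intersection test.** The null distribution of the m-fold
  intersection of sets placed uniformly in a background of size N is built
  by sequential hypergeometric mixing; p is the upper tail at the observed
  intersection and E = Πnᵢ/N^(m−1). Exactness is tested against full
  enumeration on small universes and against Fisher's exact test at m = 2.
* **GO permutation test** draws |candidates| SNPs uniformly per
  permutation, maps them to genes (span ± 2 kb; distinct genes counted
  once — gene-mode, matching a null of gene abundance and controlling for
  gene length), and reports (1 + #perm ≥ obs)/(1 + n_perm) with
  Benjamini–Hochberg q-values. Functional-class tests are two-sided
  Fisher's exact tests (the data contain both deficits and enrichments)
  with Bonferroni correction over the eight tested classes.
* **RRHO** computes one-sided hypergeometric enrichment p over all
  threshold pairs of two rankings of one gene universe, via a 2-D
  cumulative overlap count; the optimal cell (max −log10 p) defines the
  overlapping gene set. TMM factors use a 30% M-trim and 5% A-trim against
  the reference library (the sample whose 75th-percentile count fraction
  is closest to the mean), unweighted trimmed mean; the reference factor is
  1 and CPM = count/(library × factor) × 1e6. The low-expression filter is
  implemented exactly as stated (remove a gene with ≤2 CPM in ≥9 samples);
  the conventional "keep if >2 CPM in ≥9 samples" dialect is available
  behind a flag.
* **Distances and networks.** Jukes–Cantor distances are computed per pair
  on complete-case sites; p ≥ 0.75 is outside the model's domain and is
  reported undefined. Split-network construction itself is delegated to
  external software via NEXUS export (binary characters, `?` for missing);
  the clustering claim is tested quantitatively instead, with the
  permutation statistic "mean between-class − mean within-class distance".
  On desk-scale SNP-only matrices, between-karyotype mismatch fractions
  can exceed 0.75 (no invariant sites dilute them), so the simulation
  clustering tests run on p-distances; the JC correction is exercised on
  in-domain fixtures.

## Phasing filter cascade

Pool sites are usable when the pooled sires are effectively homozygous
(minor-allele fraction < 10%). A non-pool (wild) allele is reported only
if its summed count across all F1 libraries is ≥ 10 (read as summed, per
the design's wording; a per-sample variant is exposed as a flag). Within a
library, an allele must fall inside the central exact 90% binomial
interval around the heterozygous expectation of 0.5 (exact rather than a
normal approximation: well-defined at low coverage); sites with coverage
< 15 or above the library's 95th coverage percentile (nearest-rank, per
sample and chromosome) are masked. Where more than one wild allele
survives, the most frequent is kept.

## Karyotype classification

Marker panels are derived from training chromosomes of known karyotype
(F_AT ≥ 0.9, inversion-allele frequency ≥ 0.95 in inverted and ≤ 0.05 in
standard chromosomes). A sample is called from the fraction f of
informative markers carrying the inversion allele: INV at f ≥ 0.9, STD at
f ≤ 0.1, HET otherwise, UNKNOWN below 2 informative markers. The 0.9/2
defaults are deliberately conservative choices (the underlying procedure
used 4 usable markers of a 19-marker panel and excluded all ambiguity);
both are exposed parameters. HET/UNKNOWN samples are excluded from
karyotype-resolved analyses by default.

## Calibration and validation design

* **Neutral Tajima's D.** The standard neutral expectation D = 0 applies
  to recombining sequence. A single non-recombining locus tuned to S ≈ 40
  in a 20-chromosome sample has an intrinsically negative mean D
  (≈ −0.10, confirmed with an independent coalescent simulator), because
  the variance normalisation and S are correlated on a single genealogy.
  The neutral calibration therefore pools the sample site-frequency
  spectrum over 8 independent 100-kb windows per replicate (free
  recombination between windows, none within) at 2N = 200 — the regime in
  which the expectation applies and which matches how window statistics
  average over many genealogies in real data. 200 replicates run in the
  test suite; 400 in the acceptance script.
* **Equilibrium F_AT of a balanced polymorphism.** The two karyotype
  classes behave as demes of relative size q and 1−q exchanging lineages
  at the flux rate; first-step analysis of the two-deme structured
  coalescent gives expected coalescence times and hence the expected
  equal-sample Weir–Cockerham estimate (the Hudson-style ratio
  1 − mean(T₁₁,T₂₂)/T₁₂). The forward engine, run to flux–drift–mutation
  equilibrium at the scaled flux implied by the reference scenario
  (between-karyotype F_ST expectation 0.13 given neutral spatial
  subdivision F_ST 0.05 and q = 0.1), reproduces the analytic value within
  the simulation confidence interval; spatial subdivision enters through
  the multiplicative combination 1 − (1−F_a)(1−F_b) of independent
  components. The published scenario prints no effective population size
  or estimator convention, so the scaled flux is solved from the printed
  expectation itself and the claim tested is that the forward engine
  agrees with structured-coalescent theory at that operating point.
* **Pattern properties** (20 seeds each, sign tests): F_AT higher in
  breakpoint-flanking tranches than in the inversion center when
  phi_center ≫ phi_bp, with a flat-flux control showing no consistent
  direction; within-inverted-class diversity reduced at the breakpoints
  relative to the center; slower r² decay within the inverted class than
  in a neutral population of matched chromosome count; and the clustering
  contrast — inside-breakpoint sites cluster by karyotype while sites away
  from the inversion separate populations.

## Problem sizes

Test fixtures use 2N = 100–400 chromosomes, L = 1000–2000 candidate sites
on a 1-Mb chromosome, 1000–2400 generations, and 20 seeds per pattern
claim; permutation tests use 200–20 000 permutations and the GO test
defaults to 1e5 permutations with 1e4 used in tests. These sizes keep the
full suite and the acceptance script within a desktop-scale run while
leaving the Monte-Carlo intervals tight enough for the stated checks.

## Known limitations

* The inversion is a label: breakpoint-disruption effects, inversion age
  estimation from divergence, and tract-length conversion models are out
  of scope.
* The simulator is panmictic within a population; spatial structure is
  represented only through derived populations (no ongoing migration), and
  the subdivision component of the equilibrium-F_AT check enters
  analytically.
* Differential-expression modelling (voom/eBayes) is out of scope; the
  integration stage consumes ranked or thresholded DE tables, and the
  tests rank genes by simple contrasts of normalised log-CPM.
* The Neighbor-Net algorithm itself is not implemented; NEXUS export and
  the permutation clustering test cover the scientific claim.
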