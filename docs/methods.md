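# Methods

## Scope and model

`medipscape` re-implements, as a reusable and fully tested pipeline, the
statistical core of a multi-breed MeDIP-seq methylome comparison in sheep:
binned enrichment scoring of immunoprecipitation coverage, genomic-element
and CpG-island annotation, differential-methylation calling between breeds,
hierarchical clustering of breed methylomes, mitochondrial-haplotype Fst,
and integration of CpG-site methylation with qPCR expression, protein
levels and body-mass phenotypes.

MeDIP-seq read density is a **relative** methylation signal: the antibody
enriches methylated fragments, so local read counts scale with methylated
CpG content but cannot be converted to absolute 0–100% methylation. All
inference therefore operates on a depth- and length-normalised density,
the enrichment score of a genomic bin,

    score = count × 10⁹ / (width × total_unique_mapped_reads),

an RPKM variant evaluated on 300-bp bins (and on 100-kb windows for
genome-landscape tracks). Bins supported by fewer than 10 reads summed
over all samples are removed before statistics; the alternative
every-sample-under-threshold reading is available via
`filter_bins(..., per_sample=True)`.

### Read-to-bin attribution

A read belongs to exactly one bin, the one containing its strand-aware 5′
position (`start` for `+` reads, `end − 1` for `-` reads). This conserves
counts exactly and avoids fractional-overlap ambiguity. Coordinates are
0-based half-open everywhere, including all BED I/O.

### Element annotation

Promoter zones are defined around the TSS, strand-aware, using the closed
printed bounds converted to half-open intervals:
distal −2200..−1000, intermediate −1000..−200, proximal −200..+500.
A bin overlapping several features takes the highest class under the fixed
precedence *proximal > intermediate > distal promoter > exon > intron >
intergenic*, so element classes always partition the bin set. The bounds
are anchored at the TSS (not the first-exon end), and islands or bins
touched by genes on both strands resolve by the same precedence.

### CpG islands

A CpG island is any maximal merge of 200-bp windows (1-bp step) whose
observed/expected CpG ratio

    O/E = (#CpG dinucleotides × L) / (#C × #G)

exceeds 0.6 (Gardiner-Garden-style O/E; no GC% floor is applied by
default because the defining rule here is the O/E threshold alone — a
`gc_min` option exists). Windows containing N are skipped; the O/E of a
merged island is recomputed on the merged span and the island is dropped in
the rare case dilution pulls it under the threshold, so every emitted
island satisfies the definition. Islands are classed promoter
(−1000..+300 around the TSS), intragenic (TSS+300 to TES−300),
3′-transcript (TES−300 to TES+1000) or intergenic, with precedence in that
order for boundary-spanning islands.

### DMR calling

For every retained bin and every unordered breed pair (4 breeds → 6 pairs)
a two-sample **pooled-variance Student t-test** compares per-sample
enrichment scores. Welch's correction is deliberately not the default:
with two biological replicates per breed the Welch degrees of freedom
degenerate, while the pooled form is exact under equal group variances.
A bin is a DMR when any pair has raw P < 0.05; no multiple-testing
correction is applied at this stage (Benjamini–Hochberg is available
behind a flag and is used where many hypotheses are tested jointly, i.e.
gene-set enrichment). Fold change is the ratio of breed mean scores with
a pseudo-score ε = 0.01 substituted for zero means; the effect-size filter
keeps DMRs with fold change strictly above 2 or strictly below 0.5 in at
least one pair.

**Breed specificity** uses the strictest consistent rule: a bin is
specific to breed B iff all three comparisons involving B are significant
with B on the same side each time *and* no comparison among the remaining
breeds is significant. Note the rule has a hard ceiling: with three null
pairs tested at α = 0.05, at most ≈ 0.95³ ≈ 86% of genuinely specific bins
can pass even at infinite power. The exclusivity clause is switchable
(`exclusive=False`).

### Breed clustering

Breed-averaged enrichment vectors (restricted in the pipeline to
intergenic bins covered in every sample) are clustered by average linkage
under the distance 1 − Pearson correlation. Leaf order is made
deterministic by sorting unit labels before building the linkage; the tree
is exported as Newick. Average linkage on a proper dissimilarity yields
monotone merge heights, which the tests assert.

### Haplotype Fst

Aligned sequences are collapsed to haplotypes by exact identity after
uppercasing and complete deletion of alignment columns containing gaps or
ambiguity codes. Pairwise Fst is the two-level AMOVA fixation index on
haplotype-identity (0/1) distances,

    Fst = σ²_among / (σ²_among + σ²_within),

equivalent to the haplotype-frequency form of Weir–Cockerham θ; slightly
negative estimates are reported as computed (they are legitimate when
within-population variation dominates). Significance comes from permuting
individuals between the two populations with the add-one estimator
p = (1 + #{Fst_perm ≥ Fst_obs}) / (n_perm + 1), deterministic under a
seed. Distance-weighted ΦST is out of scope; repeat-region trimming is
assumed done upstream.

### qPCR and phenotype integration

Relative expression follows E^(−ΔΔCt): technical wells are averaged per
sample/gene, ΔCt subtracts the arithmetic mean of the reference-gene Cts
(ACTB and RPL19 by default; arithmetic Ct mean equals geometric-mean
quantity normalisation at common efficiency), ΔΔCt subtracts the mean ΔCt
of a named calibrator group, and expression is E^(−ΔΔCt) with E = 2.0 by
default (per-gene override available). Per-CpG-site breed differences use
the same pooled t-test as the bin statistics. Methylation–expression and
methylation–protein association is the Pearson correlation with the exact
t-based P-value (t = r√(n−2)/√(1−r²)); zero-variance inputs produce
missing values, never fabricated numbers. The body-mass phenotype is
MBMI = weight / length² (kg/m²).

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes, with the
dependence structure the analysis assumes. Defaults define the emulated
study: 4 breeds (UQ, Tan, StH, Hu) × 2 replicates, a 600-kb two-chromosome
genome tiled into 2,000 bins of 300 bp, 60 genes, 120 planted
breed-specific DMR bins at 4-fold propensity difference, 600,000 reads per
sample (≈300 reads per bin on average), 4 populations × 40 haplotyped
individuals, and 9 muscle samples (3 breeds × 3) with two
methylation-coupled target genes of opposite slope sign.

* **Genome.** The background sequence is generated CpG-free (every CG
  dinucleotide broken) — an idealised extreme of the CpG depletion of
  methylated vertebrate genomes. This makes island detection exactly
  decidable: a window's O/E can spike on a handful of chance CpGs when C
  or G are scarce, so any residual background CpG rate would produce
  sporadic false islands. Island tracts (~0.02 of the genome, 400–1200 bp)
  are CpG-dense and GC-rich; half are placed at gene promoters.
* **Coverage.** Per-bin sampling propensity = element baseline (exon 2.0,
  intron 1.0, intergenic 0.8, promoters 0.7–1.2, promoter-CGI bins ×0.25)
  × shared lognormal bin heterogeneity (sd 0.8) × planted DMR fold ×
  optional breed-divergence factor, CpG-weighted by 1 + CpG count/width.
  Reads are multinomial with per-bin lognormal replicate noise (sd 0.05).
  The noise and heterogeneity scales were calibrated jointly so that
  default settings reproduce within-breed replicate Pearson correlations
  ≈ 0.99 while planted 4-fold effects remain detectable by an n = 2 vs 2
  t-test; `simulate_bin_counts` provides the count-level distribution
  without materialising read records for large count-only experiments.
* **Haplotypes.** K = 12 root haplotypes derive from one ancestor by
  disjoint private mutations; population frequencies interpolate between
  a shared Dirichlet base vector (divergence 0) and fixation for distinct
  haplotypes (divergence 1).
* **Expression.** Target Ct = baseline − slope × methylation + noise, so a
  positive slope yields a positive methylation–expression correlation;
  at the default slope ±3 over methylation ~ U(0.3, 0.7) and Ct noise
  0.17 the planted correlation magnitude is ≈ 0.9 at n = 9.

Not modelled: fragment-size/sonication effects, antibody affinity,
sequencing errors, mappability and GC bias, linkage between sites,
recombination, batch effects, and real CpG background rates. Passing
tests therefore demonstrate correctness of the statistics and the
pipeline's behaviour under its own assumptions, not performance on real
sequencing data.

## Validation design and problem sizes

Problem sizes were chosen for desk-scale runs: the default simulation
(2,000 bins, 4.8 M reads) drives replicate QC, DMR counting and profile
checks; null t-test calibration uses 10,000 bins at the default per-bin
coverage (3 M reads/sample, counts path) averaged over three simulations
and is compared to the 99% binomial band at n = 10,000; planted-DMR
recovery aggregates five simulations (600 planted bins); clustering
recovery runs 100 seeded simulations of a 400-bin genome with one
methylome-divergent breed (lognormal divergence sd 0.35); coupling
recovery runs 100 seeded expression simulations. Permutation tests use
1,000 permutations. Brute-force oracles (naive interval scans, exhaustive
window enumeration, literal AMOVA double loops, closed-form tails) verify
the vectorised implementations exactly or to 1e-10.

## Numerical choices and degenerate inputs

* Zero-variance-in-both-groups bins get t = 0, p = 1 (no within-group
  information), and zero-variance correlation inputs return missing.
* Fold changes guard zero means with ε = 0.01.
* An all-identical pooled haplotype sample has no variance to partition;
  Fst is defined as 0 there. Fixed differences give exactly 1.
* Empty annotation classes report missing means, never zero.
* The last bin of each chromosome is truncated; bins always partition the
  chromosome exactly.
* All randomness flows through `numpy.random.Generator` seeded per stage
  from the configuration seed, making every output byte-reproducible.

## Known limitations

Raw-P DMR calling at P < 0.05 with n = 2 per group is faithful to the
analysis it reproduces but statistically permissive; the BH option exists
for stricter use. The breed-specificity ceiling (~86%) is inherent to the
exclusivity rule. Haplotype Fst ignores the mutational distance between
haplotypes. The qPCR model treats amplification efficiency as a constant
base rather than estimating it from dilution curves.
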