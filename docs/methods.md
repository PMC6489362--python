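# Methods

## Model and procedure

The quantity of interest at a heterozygous SNP is the allelic read fraction
of a ChIP-seq mark: with k of n informative reads carrying the haplotype-1
allele, the no-imbalance null after diploid realignment is k ~ Binomial(n, ½).
Aligning every read to *both* personal genomes and assigning it to the
haplotype it matches better removes reference bias by construction — a read
carrying the alternative allele is never penalized against a reference-only
genome, so ½ is the correct null without empirical bias correction.

The test is the exact two-sided binomial p-value, p = min(1, 2·min(P(X≤k),
P(X≥k))), computed by tail summation (no normal approximation; sites are
often at n of a few dozen where the approximation is poor). Correction for
genome-wide testing uses Benjamini–Hochberg within each mark across all
tested sites, after which a site is an AS-SNP if q ≤ `fdr` in at least one
mark and it survives exclusion-region filtering. Bonferroni and pooling the
marks before correction are available via configuration; per-mark BH is the
default because the marks are separate experiments with very different site
sets and signal strengths, and the catalog is defined as the union of
per-mark discoveries.

Design choices in the test stage that the data do not pin down:

* **Minimum informative coverage** `min_total = 10`. Below ~10 reads the
  discrete test cannot reach p < 0.05 two-sided (n = 9 gives p ≥ 2·2⁻⁹ ≈
  0.004 only at k ∈ {0, 9}, and BH across thousands of sites pushes the
  effective threshold far lower), so testing such sites only dilutes the
  correction. Configurable.
* **Ties.** A read matching both genomes equally overlaps no heterozygous
  difference (or balances errors); it carries no allelic evidence and is
  excluded from counts but retained in coverage reporting.
* **Counting keys on the observed base** at the SNP column, not on the
  read's overall genome assignment: a read spanning two het sites
  contributes per-site evidence correctly even if one base is erroneous.
  Bases matching neither haplotype allele go to `count_other` and are never
  tested, so sequencing error cannot masquerade as allelic signal.
* **Allelic ratio** is reported as count_g1/total for the mark with the
  smallest q-value.

## Alignment

The internal aligner is deliberately ungapped: personal genomes differ from
the sample's reads only by substituted SNVs and base errors, so candidate
loci are found by exact 16-mer seeds (three seed offsets per read, both
strands) and scored by full-length Hamming distance against both genomes at
the same coordinates (the genomes are equal-length by construction). A read
is UNMAPPED if its best placement exceeds `max_mismatches = 3` or if two
distinct loci tie for best — the conservative choice for duplicated regions.
Reads with mean base quality below Phred 20 are screened out before
alignment; the Phred-20 floor is also applied per base at the counting step.
The mean-vs-per-base reading of a quality cutoff is ambiguous in general, so
both are applied and both are configurable. Externally produced per-genome
SAM alignments can be ingested instead (`import_alignment_pair`), taking
mismatch counts from NM tags or recomputing them from the loaded genomes.

Indel-aware coordinate lifting is out of scope: the allele-specific analysis
is SNV-only, and substitution-only genomes keep shared coordinates, which is
what makes per-site haplotype counting trivial and exact.

Homozygous-alt variants are substituted into both genomes (they affect read
placement) but never tested — only heterozygous sites are informative about
allele-specific signal.

## LD, GWAS, eQTL, loci

r² between two sites is the squared correlation of allele indicators across
phased haplotypes, D²/(p_A(1−p_A)p_B(1−p_B)); it can be computed from a
phased panel or taken from a precomputed pair table, and proxy expansion
uses the strict inequality r² > 0.8. GWAS and eQTL matching is positional
(one genome build is asserted); rsid matching is secondary since synthetic
data carries no dbSNP identifiers. "Loci" are built by single-linkage
chaining — consecutive sorted AS-SNPs on one chromosome join a locus iff
their gap is ≤ 1 Mb — rather than fixed bins, because chaining is invariant
to input order and to bin phase; fixed binning is available in configuration
for sensitivity analysis. An AS-SNP proxied by several GWAS SNPs is
annotated with its strongest link (largest r²).

## Motif scoring

PWM matrices (JASPAR-style counts) get an additive pseudocount (0.01) and
per-position renormalization. A placement's raw score is the summed log₂
odds against a uniform background; scores are normalized to [0, 1] by the
PWM's attainable minimum and maximum so that a score *change* of 0.3 is
comparable across motifs of different length and information content (on an
unbounded log-odds scale a fixed change threshold has no portable meaning).
Per allele, the best normalized score over all placements × strands
overlapping the SNP is taken — an allele may shift the optimal register —
and the score change is the absolute difference of the two bests. The
candidate-functional rule is:

    DNase present AND TF expressed AND Δscore ≥ 0.3
    AND (TF ChIP binding event OR functionality score ≥ 2.55)

The functionality score is a weighted sum of tissue annotations on the
motif placement. The shipped weights (binary tracks 1.0; active chromatin
states 1.0, quiescent 0.0; replication domains 0.25) are explicit
placeholders chosen so the 2.55 threshold is exercisable on synthetic
annotation tracks; the weight set behind the published threshold is not
public, and any real analysis should supply its own calibrated weights in
the config. The expression floor for "TF expressed" is value > 0,
configurable.

## Synthetic data: what it emulates and what it does not

The generator emits a complete miniature study: uniform-base reference
(default 2 × 200 kb), phased SNVs on a jittered grid (mean spacing 300 bp;
heterozygous fraction 0.5, close to the ~51% observed in deep WGS of a
single individual; 5% non-PASS records to exercise VCF filtering),
non-overlapping ChIP-seq peaks per mark centered on het PASS variants,
single-end 100-bp reads from 200-bp fragments at 80 fragments per peak, a
per-base error rate of 10⁻³, and planted allelic imbalance (ratio 0.8) at 9
sites across the three default marks (CTCF, H3K4me3, H3K27ac). Two planted
sites are additionally covered by blacklist intervals, three carry planted
PWM consensus motifs where the two alleles are the consensus and the worst
base at the motif's most informative position, and planted GWAS/eQTL/LD
links come with a 100-haplotype phased panel whose haplotype counts realize
each requested r² on the achievable grid ((k/25)², nearest value recorded in
the manifest).

Deliberate simplifications, and hence what passing tests do *not* show about
real data:

* **Fragment counts are fixed** at the configured coverage (a degenerate
  "mean"), and base qualities are two-valued (Q30, Q10 at injected errors),
  so the Phred-20 filter and coverage thresholds are exercised
  deterministically. Real libraries have dispersed coverage and quality
  distributions.
* **Haplotype draws are independent per site and fragment**; real fragments
  covering two het sites are haplotype-coherent. The counting stage is
  per-site, so this does not affect what is tested, but haplotype-level
  aggregation methods could not be validated on this generator.
* **Motif planting controls the flanking bases** around the planted
  consensus (the dominant position's base appears once, its complement not
  at all, and flanks cannot present it on either strand), making the planted
  normalized score change deterministic (≈ 0.72) rather than
  sequence-context dependent.
* No mappability structure, duplication, indels, CNV, or linked-read
  barcode structure; reference bias itself is not simulated (reads are
  drawn from haplotypes symmetrically), so the pipeline's bias *removal* is
  validated by construction, not against a biased aligner.
* One pseudo-random stream per output file, all derived from the master
  seed, so adding a mark or track leaves other files byte-identical.

## Numerical and calibration choices

* Binomial tails via scipy's exact binomial distribution; the test suite
  pins agreement with full-outcome enumeration in exact rational arithmetic
  for all (k, n), n ≤ 20.
* BH is a direct step-up implementation (sorted p·m/rank, reverse cumulative
  minimum, capped at 1), cross-checked against statsmodels in tests.
* FDR calibration and power-recovery studies run at the count level
  (Binomial draws per site), which is exactly the distribution the
  read-level pipeline induces at error-free sites: 100 replicates × 2500
  all-null sites at coverage 30 for calibration, and 150 planted sites
  (ratio 0.8, coverage 60) among 2000 nulls for recovery, compared against
  exact binomial power at the realized BH threshold within three standard
  errors. These sizes keep the whole suite under a minute while leaving
  Monte-Carlo error well below the tolerances tested.
* Degenerate inputs: zero usable VCF records, no testable sites, empty BED
  tracks, monomorphic panel sites (r² undefined → explicit marker), and
  windows clipped at chromosome ends are all handled explicitly and
  covered by tests.

## Known limitations

* The binomial model ignores overdispersion (beta-binomial behavior from
  copy-number variation or ChIP efficiency); sites in CNV regions can show
  imbalance without regulatory meaning. Blacklist filtering removes only
  catalogued artifact regions.
* Candidate-functional calling inherits whatever annotation tracks are
  supplied; with the placeholder weights the functionality score is a
  demonstration, not a calibrated quantity.
* The internal aligner targets desk-scale synthetic studies; for real
  libraries, align externally per genome and ingest the SAM pair.
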