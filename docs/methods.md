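# Methods

## Problem and model

`sdrase` targets the allelic signature of a suppressed-recombination
sex-determining region (SDR) in a male-heterogametic (XY) dioecious plant.
The observable unit is a *site observation*: ref/alt read depths for one
nucleotide site in one sample (DNA or cDNA, per tissue).  Three signals
are modeled:

* **DNA heterozygosity.**  At a heterozygous site, genomic allele depths
  are symmetric around 0.5.  A site is called het when its alternative
  fraction falls in the band [0.2, 0.8] at ≥ 20× depth.  Outside the band
  the minor count is compared with the sequencing-error rate by a
  two-sided exact binomial test (α = 0.05): consistency with error gives
  a homozygous call, inconsistency leaves the site undetermined.  The band
  plus depth floor operationalize "fraction about 0.5" robustly at both
  WGS (≈ 20×) and amplicon (≈ 2,000×) depths — at amplicon depth a pure
  binomial test would reject 0.5 for biologically irrelevant deviations,
  which is why an interval rule, not a test, defines heterozygosity.
* **Monoallelic expression.**  At DNA-het sites, cDNA with major-allele
  fraction ≥ 0.9 is monoallelic, in (0.1, 0.9) biallelic, below 20×
  undetermined.  A gene × individual call requires ≥ 2 informative site
  calls and agreement of ≥ 80 % of informative sites within *every*
  tissue that has informative sites; tissues disagreeing on the verdict
  leave the gene undetermined.  Phase is not required: each site must be
  individually monoallelic, but the dominant alleles need not be assigned
  to one haplotype (phase is unknown in real data; the simulator's truth
  tables allow a stricter phased check if wanted).
* **Y hemizygosity.**  Sequence present only on the Y shows ~half-depth
  male WGS coverage and zero female coverage.  Depth is binned (200 bp
  over the 120-kb SDR window, 600 bins), each sample is normalized by its
  median bin depth (the median is robust while candidate bins are a
  minority of the window; the normalization scheme is this package's
  choice), and male-specific intervals are maximal runs of ≥ 2 bins with
  male normalized depth ≥ 0.3 and female ≤ 0.1.  The 0.3/0.1 pair
  separates a 0.5-copy male signal from Poisson noise at ≥ 15×; the run
  rule suppresses single-bin noise.

The cohort-level statistic is a one-sided Fisher exact test per gene on
sex × {monoallelic, biallelic}, directed toward the sex with the larger
monoallelic proportion (males on ties), with undetermined individuals
excluded rather than imputed.  Fisher's exact test is used because the
cohort is small (n = 20); one-sided because direction is part of the
claim.  No multiple-testing correction is applied by default (the panel
has three genes); Bonferroni over the panel is available via
configuration.

## Synthetic cohort generator

Read-level simulation is deliberately abstracted to allele-depth sampling:
the depths are the sufficient statistic for every downstream stage, so no
FASTQ/BAM or reference sequence is involved.  At a site with true
alternative-allele fraction *f*, total depth is Poisson(λ) and the alt
count is beta-binomial with mean p\* = f(1−e) + (1−f)e and intraclass
correlation ρ (ρ = 0 degenerates to binomial).  Defaults: sequencing
error e = 0.005 (mid-range Illumina after filtering), overdispersion
ρ = 0.02 (mild amplicon/library overdispersion), site QUAL 60.

The generated design mirrors the study layout:

* bulk pair: one male (WGS 18×) and one female (26×), cDNA of leaves,
  catkin axes and flowers at 100× informative depth — six RNA libraries;
* amplicon cohort: 10 males + 10 females, DNA from leaves plus cDNA from
  the three tissues at 2,000× — 80 samples over the expressed gene panel;
* five SDR genes with the published Stettler-14 coordinates; TCP, CLC and
  MET1 transcribed (200 expected counts/library), NB-ARC and the unknown
  gene silent; the CLC-like gene has Y-allele expression fraction 0 in
  males (complete Y silencing), all others 0.5;
* one 4-kb Y-hemizygous interval (Chr18:16,290,000–16,294,000, intergenic
  within the SDR window), untranscribed;
* every individual is heterozygous at every simulated site (the
  intersectional-hybrid premise), four sites per gene.

The bulk count matrix adds 1,000 background genes with log-normal base
rates (ln-mean 4.5, ln-sd 1.2), mild log-normal tissue modulation, and a
tissue-dependent sex-biased fraction (leaves 4 %, catkin axes 15 %,
flowers 22 %, four-fold effects in random directions).  These fractions
emulate the observed ordering of sex differences (vegetative ≪
generative tissues) and give the distance matrix its leaf-pair <
flower-pair male–female structure; they are design constants, not
estimates.

Randomness uses a single global seed; every draw comes from a substream
keyed by a stable CRC-32 hash of (individual, material, tissue, site), so
enlarging the cohort leaves existing individuals' data bit-identical.

What the generator does **not** emulate: mapping bias and alignability
(monoallelic calls in real data can be inflated by reference bias),
isoform structure, positional coverage waves, amplicon primer dropout,
genotype-specific het-site sets (real individuals differ in which sites
are heterozygous; simulated individuals share the site panel), and
linkage between the hemizygous interval and gene content.  Passing tests
therefore demonstrate correctness of the statistical machinery on an
idealized depth model, not robustness to alignment artifacts.

## Numerical choices

* Coordinates are 0-based half-open internally; GFF3 and printed 1-based
  inclusive coordinates convert at the I/O boundary.  The final partial
  coverage bin is kept truncated, not dropped.
* TMM follows the standard trimmed-mean-of-M-values procedure: reference
  library = closest upper-quartile proportion to the mean; M-values
  doubly trimmed (30 % on M, 5 % on A); inverse-asymptotic-variance
  weights; factors rescaled to unit product.  The implementation was
  validated against edgeR's `calcNormFactors(method="TMM")` on a
  composition-biased toy matrix (agreement to 7 significant digits; the
  values are frozen in the test suite).  Note that exactly doubling a
  library leaves factors at 1: TMM corrects composition, library size is
  handled by CPM.
* The DEG screen applies the fold-change rule to TMM-adjusted CPM with a
  0.5 pseudo-count added to group means before the ratio; the CPM > 8
  floor is evaluated on unshifted means.  No dispersion estimation or
  p-values: the screen implements exactly the published CPM/fold-change
  definition, and replicate structure for a likelihood test is absent in
  the two-individual bulk design.
* The Spearman distance filter ("average CPM > 16") averages over all
  libraries; ties get average ranks; constant rank profiles raise an
  error rather than emitting NaN.
* Genes are treated as opaque spans (UTR status of the printed
  coordinates is unknown); the chromosome name is an opaque label (the
  SDR sits on chromosome 18 in the reference assembly used, though
  genetic maps place it on chromosome 19).

## Problem sizes used in tests and the acceptance script

Planted-pattern recovery is checked over 100 simulated cohorts at the
full study design; the null false-positive rate over 500 reduced cohorts
(3 sites/gene, 500× amplicon depth, no background genes — the Fisher
test's validity does not depend on depth, and the reduction keeps the
suite fast); the genotype-caller operating point over 2,000 sites at 30×;
hemizygous-interval recovery at 20× WGS.  The acceptance script runs the
complete default design once per seed.

## Known limitations

* Variant discovery is out of scope: only sites present in the input VCF
  are genotyped, and the QUAL filter applies to the site, not per-sample
  genotype qualities.
* Multi-allelic records are decomposed ref-vs-alt pairwise; third alleles
  never contribute to fractions.
* The hemizygosity caller reports interval unions of qualifying bins; it
  does not resolve breakpoints below bin resolution and does not model
  repeats or copy-number > 2.
* With exactly one informative tissue the cross-tissue consistency rule
  degenerates to a single-tissue call.
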