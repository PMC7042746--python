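# Methods

## Setting and data model

The pipeline evaluates candidate SNPs for local adaptation in a cohort with
two focal populations (sizes 25 and 40 by default) embedded in a wider
panel (875 samples by default).  Genotypes are biallelic SNPs stored as a
dosage matrix.  The default encoding is **haploid** ({0, 1}, heterozygous
calls set to missing): the intended organisms are highly selfing, so
residual heterozygous calls are more likely errors than true heterozygotes.
A diploid {0, 1, 2} mode is available (`ploidy=2`), in which heterozygotes
count one alternate allele.  How heterozygotes in such panels were
historically treated is not documented anywhere authoritative; the
missing-by-default policy is this package's choice and is configurable
(`het_policy` ∈ {missing, ref, alt}).

Coordinates are 1-based inclusive everywhere internally (the native VCF and
GFF3 convention); BED-family inputs are converted at the read boundary and
converted back on export.  The genome-wide variant order — which defines the
rotation axis for the permutation null — sorts chromosomes
lexicographically unless an explicit order is supplied.

## Per-SNP statistics

**Allele frequencies and AFD.**  For population P, the alternate-allele
frequency is Σ(dosage)/(ploidy × n_non-missing); a site with no non-missing
call in P is missing.  AFD = |f_A − f_B|.  AFD is invariant under swapping
which allele is labelled reference.

**MAF filter.**  Sites are retained when the panel-wide minor allele
frequency strictly exceeds the threshold (default 0.05).  The strict
inequality matters at the boundary: a site at exactly 0.05 is removed.

**Windowed LD.**  The LD of a SNP is the mean of squared Pearson
correlations between its dosage vector and each neighbouring SNP on the
same chromosome within `ld_window_bp` (default 20,000 bp), excluding
itself.  Two window readings exist in the field; both are provided:

* `distance` (default): neighbours with |Δpos| ≤ 20 kb — the pairwise
  distance reading, the common convention for windowed r²;
* `centered`: |Δpos| ≤ 10 kb, i.e. a window of 20 kb total span.

Correlations use pairwise-complete samples.  A pair with fewer than two
shared samples or zero variance on either side has no defined correlation
and is excluded from the mean (it does **not** contribute r² = 0); a SNP
with no defined pair is missing.  The implementation is blocked matrix
algebra over sums and cross-products of the zero-filled dosage and the
missingness mask, which reproduces the naive per-pair computation exactly
(dosages are small integers, so the sums are exact in double precision);
the suite checks agreement with a brute-force oracle to 1e−10.  Two LD
columns are produced: over the 65 focal samples and over the full panel.

**Derived allele frequencies.**  Given a per-site ancestral base and
probability, the derived allele is the one differing from the ancestral
base; DAF is its panel frequency.  DAF is missing when the ancestral
probability is ≤ 0.6 (strictly greater is required) or the ancestral base
matches neither allele.  DAFs are computed on the post-MAF-filter panel
(whether the historical analyses filtered first is not documented; applying
the same filter to every downstream statistic keeps the variant set
consistent).  Spectra use left-closed right-open bins with the last bin
closed, so a boundary value such as 0.5 falls in the upper bin.

**AFD.LD candidate rule.**  Thresholds are the empirical 95th percentiles
(numpy's linear interpolation between order statistics) of the genome-wide
non-missing AFD and focal-LD distributions, or a fixed pair
(0.70, 0.19 shipped) in `threshold_mode: fixed`.  The comparison is strict
on both axes; fewer than 20 non-missing values abort (a percentile from
fewer points is too unstable to threshold on).  On a panel where AFD and LD
are independent, 95/95 percentile calling flags ≈ 0.25% of SNPs; real and
simulated panels flag far more because the two statistics co-occur at
swept loci — on the default synthetic cohort the planted blocks dominate
both tails.

**Window scan.**  Windows of 20 kb advance in 1-kb steps from the first SNP
of each chromosome; each reports qualifying/total SNPs, with an empty
window carrying a missing ratio.

## Functional annotation

**Cis-regulatory intervals.**  For each gene, the 1-kb stretch immediately
upstream of the TSS (genic start on +, genic end on −), clipped at the
chromosome start, minus every base lying inside another gene's genic span —
where "genic span" is the full gene extent including UTRs and introns (the
natural reading of a gene feature's extent; no finer definition is
warranted by the inputs).  The subtraction can fragment or empty the
interval.  Consequently a base in some gene's CDS can never be
cis-regulatory; when two genes' cis intervals overlap, a SNP there counts
once for proportion tests but is assigned to both genes for gene-level
tests.

**Coding changes.**  The codon containing a SNP is rebuilt from the spliced
CDS in transcript orientation (reverse-complemented on −), honouring the
phase of the transcript-first CDS segment; both alleles are translated with
the standard genetic code.  Stop is a distinct symbol, so stop gain/loss is
nonsynonymous — the classification only distinguishes synonymous from
nonsynonymous.  Genes whose summed CDS length is not a multiple of three
are flagged non-codable and their SNPs stay "other" (logged).  For
multi-transcript genes the first mRNA (by identifier) carrying CDS features
is used.  Rebuilding codons requires the reference sequence, so the
annotation stage takes a FASTA alongside the GFF3; a mismatch between the
FASTA base and the VCF reference allele is logged and the VCF allele wins.

**Conserved blocks.**  Maximal runs of ≥ 10 consecutive scored bases with
score ≥ 0.8.  Unscored bases break runs rather than counting as zero:
absence from an alignment is absence of evidence, not evidence of
non-conservation.

**Site classes.**  Precedence coding > cis-regulatory > other; the
constraint flag is independent of class.

## Circular-permutation enrichment

The null rotates the genome-ordered selection vector (a q-value threshold
indicator, or the AFD.LD candidate flag rotated as a unit) relative to the
fixed positions and annotations, following the indexing
`shifted = x[c(k:n, 1:(k−1))]`: the value at rank k moves to rank 1, and
offset 1 is the identity.  Rotation is over the single concatenated
genome-wide vector — chromosome boundaries are deliberately ignored, which
keeps the null exchangeable over the whole SNP order.  Offsets are drawn
uniformly from 1..n **with replacement**, identity allowed: with n in the
tens of thousands the identity draw is negligible and the uniform draw
keeps the null exactly exchangeable.

Every rotation preserves the number of selected SNPs and the genome's
category layout, so the null mean of the proportion-in-category equals the
overall category density.  The empirical p-value uses the +1 correction,
p = (1 + #{null ≥ observed})/(B + 1), which can never return 0; the
historical decision rule — observed strictly above the 95th percentile of
the null — is reported alongside as `significant`.  Degenerate tests (no
SNP selected) are flagged invalid, not fatal.

Three categories are built on this machinery: proximity within 100 kb of
the nearest same-chromosome QTL peak; constrained cis-regulatory and
constrained nonsynonymous sites; and gene-level counts (number of listed
genes containing ≥ 1 qualifying SNP in their cis interval or CDS, the
qualifying rule in the pipeline being *selected and functional*).

**Distance decay.**  SNPs are binned by distance to the nearest peak into
10 bins of 100 kb (SNPs beyond 1 Mb or on peak-less chromosomes are
dropped), and an OLS line of per-bin candidate proportion on bin midpoint
is fitted when ≥ 3 bins are non-empty (slope per bp, R², two-sided p).  A
perfectly flat profile is reported as slope 0, R² 0 by convention rather
than as an undefined correlation.

## Synthetic cohort generator

Genotypes are simulated **directly at the frequency level** — every
downstream statistic depends only on frequency and correlation structure,
so a coalescent would add cost without adding test power.  Default scale:
two 1-Mb chromosomes, 20,000 SNPs, 875 samples (25 + 40 focal), 10 QTL
peaks — about half a minute end to end on one CPU.

* **Neutral background**: ancestral frequency ~ Uniform(0.05, 0.95); focal
  population frequencies drawn from a Balding–Nichols Beta around it with
  F = 0.005 (weak drift: at 25 + 40 samples the chance of AFD > 0.7 by
  drift alone is a rare tail, as one replicate of the suite verifies).
* **Planted divergent loci** (100): focal frequencies at the targets
  0.95 / 0.05 (AFD 0.90), panel remainder at 0.5; loci are spread over
  evenly sized strata of each chromosome's SNP index so blocks never
  collide.
* **LD blocks**: the 10 SNPs following each planted locus are noisy copies
  of its column with per-sample flip probability ε (default 0.05).  For a
  flip-noise copy, r = (1−2ε)·Var(X)/√(Var(X)·Var(Y)) gives the
  closed-form expected source-to-member r² of (1−2ε)²·v/((1−2ε)²·v+ε(1−ε))
  with v = Var(X) — ≈ (1−2ε)² at intermediate frequencies, which the tests
  use as the recovery target (±0.05).
* **Low-derived-frequency class** (10% of SNPs): derived frequency
  ~ Uniform(0.01, 0.09) in all populations, ancestral base confidently
  called as the major allele, emulating the rare-allele tail of the derived
  spectrum.
* **Ancestral calls** elsewhere: 15% below the 0.6 usability threshold.
* **Annotations**: non-overlapping two-exon genes with valid phase and CDS
  length divisible by three; conservation blocks (score 0.8–1.0, length
  ≥ 10) cover a configurable fraction of planted loci while all other
  scored intervals avoid them, so the planted-constrained overlap is exact
  at the extremes 0 and 1; QTL peaks within 10 kb of a subset of planted
  loci plus uniform decoys; q-values with 5% significant, half of the
  significant mass on the low-frequency class.
* **Missingness**: 2% uniform.

Identical config + seed gives byte-identical output files; all randomness
flows from one `SeedSequence` through named substreams.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic demography and site-frequency spectra,
recombination-driven LD decay (LD here is block-shaped, not
distance-decaying), gene density and structure of real annotations,
reference bias in ancestral calls, and any genotype–environment association
model (the emitted environmental covariate is a labelled placeholder).
Tests therefore demonstrate correctness of the *statistics and the null
machinery*, not the field performance of candidate scans.

## Numerical and design choices

* Percentiles: linear interpolation between order statistics; thresholds
  applied strictly (>).
* r² terms with zero variance or < 2 shared samples: excluded, not zero.
* Empty DAF input: an error, not an empty spectrum.
* Rotation offsets out of 1..n: an error (no silent modulo).
* Proportion with zero selected SNPs: missing + invalid flag.
* The `stats`/`annotate`/`enrich`/`scan` stages communicate through TSV
  files with run manifests (parameters, input checksums by file name,
  package version; no timestamps) so reruns are byte-comparable.
* Problem sizes in the test suite and acceptance script (1,500–6,000 SNP
  genomes, 100–875 samples, 200-rotation nulls for calibration replicates)
  are chosen so the whole validation runs in minutes on a single CPU while
  keeping every Monte-Carlo bound well inside its stated tolerance.

## Known limitations

* Gene-level assignment uses one transcript per gene; isoform-specific
  effects are out of scope.
* The permutation null treats the SNP order as exchangeable after
  rotation; strong chromosome-scale heterogeneity (e.g. one chromosome
  with a much denser category) is preserved in the null only through the
  single concatenated layout.
* The distance-decay regression is descriptive OLS on binned proportions;
  it inherits the usual caveats of regressing on aggregated bins.
* F_ST estimators, haplotype statistics (EHH/iHS), composite-likelihood
  sweep scans, imputation, phasing and multiallelic decomposition are
  deliberately out of scope.
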