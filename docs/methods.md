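# Methods

This note documents the models and procedures implemented in `norfscan`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Coordinates and intervals

All internal coordinates are 0-based half-open. GTF I/O converts from the
1-based inclusive convention at the boundary (+1 on write, −1 on read of
start positions); BED I/O passes through. Chromosome names are normalized
to a `chr` prefix on read. Interval merging treats bookended intervals
(end == start) as mergeable, matching the dominant convention of
interval-merge tools, and never consults strand; strand matters only where
an operation states it (TE upstream windows, transcript matching, frame
classification). One assembly per run is assumed; no coordinate lift-over
is performed.

## nORF curation

**Low-noise filter.** Ribo-seq counts are converted to TPM
(rate_i = count_i / length_i, scaled so each sample sums to 1e6). ORFs are
sorted by mean TPM — stable sort, ties broken by ORF id — and cut into Q
contiguous bins whose sizes differ by at most one (default Q = 4000,
capped at the number of ORFs by the pipeline with a warning for desk-scale
inputs). Canonical and non-canonical ORFs are binned jointly, so each bin
compares nORFs against canonical ORFs of similar mean abundance. Within a
bin, a non-canonical ORF is low-noise iff its SD (sample SD, n−1
denominator) is strictly below the median SD of the bin's canonical ORFs.
Bins with no canonical ORF flag nothing and are reported. The flagged set
is invariant to sample order and to monotone relabeling of ORF ids.

**Frame classification.** An nORF's codon phase is projected through
shared exonic bases in spliced coordinates (not genomic distance — the
biologically coherent choice for multi-exon CDS): base g in an exon chain
gets offset = position in transcription order, and phase = offset mod 3.
A base covered by both the nORF and a same-strand CDS with matching phases
makes the nORF `in_frame_cds`; mismatching phases `alt_frame_cds`;
transcript-span overlap without same-strand CDS overlap `non_cds`;
otherwise `intergenic`. When several transcripts overlap, in-frame takes
precedence. nORF lengths that are not a multiple of 3 raise a warning and
are classified on the first overlapping codon. In-frame nORFs are removed
unless their category is readthrough, extended/extension, uORF or
truncated/truncation. Deduplication collapses identical
(chrom, strand, exon chain) records, keeping the lexicographically
smallest id and recording the rest as aliases.

## Transcript matching

A transcript is retained when strictly more than `tpm_min` (default 0.1)
TPM is observed in at least ceil(`sample_frac` × n_samples) samples
(default 10%). Pseudoautosomal features are removed by span overlap with
configured PAR intervals or by the `_PAR_Y`/`_PAR_X` id suffix. Intron
chain equality ("=") is decided on ordered junction lists and only for
multi-exon pairs; single-exon nORFs rely on containment. Containment
requires every nORF exonic base to be covered by the transcript's exon
union and every internal nORF junction to be a transcript junction;
terminal nORF exon ends may sit inside a transcript exon. Matches
additionally require same chromosome and strand (the frame and biotype
logic presuppose it) and transcript biotype ≠ protein-coding; a missing
biotype is treated as non-protein-coding and logged.

## Differential expression

**TMM.** The implementation follows the published trimmed-mean-of-M-values
algorithm: reference sample = the one whose 0.75 count quantile (scaled by
library size) is closest to the mean; M and A computed over features
positive in both sample and reference; double trimming (30% on M, 5% on A
by ranks); precision-weighted mean of the surviving M values with inverse
binomial-variance weights; factors rescaled to geometric mean 1. Factors
are only approximately invariant to rescaling one sample's counts — the
precision weights depend on count magnitude — which matches the behaviour
of the reference implementation (cross-checked in the tests to 1e-8).

**Mixed model.** Per transcript, y = log2(CPM + 0.5) is fitted with fixed
covariates plus a diagnosis indicator and a random intercept per
individual. REML is profiled down to λ = σ_b²/σ_e² ≥ 0: for the
block-diagonal V = I + λZZ', GLS quantities are computed per group in
closed form and the scalar criterion log|V| + log|X'V⁻¹X| +
(n−p)·log(r'V⁻¹r) is minimized by bounded 1-D search (λ ∈ [0, 1e4],
tolerance 1e-8), always comparing against the λ = 0 boundary. When every
individual contributes one sample the fit reduces exactly to OLS. The
diagnosis contrast is tested with a Wald t statistic on n − rank(X) − 1
degrees of freedom — a deliberate approximation (no Satterthwaite); null
simulations show type-I error within [0.03, 0.07] at nominal 0.05 and a
uniform p distribution. Singular designs raise an error naming the aliased
columns; non-convergence falls back to OLS with a logged flag;
zero-variance transcripts are skipped and reported.

**FDR and DE nORFs.** Benjamini–Hochberg step-up with NaN p values
propagated and excluded from the test count. DE transcripts are q < 0.05;
DE nORFs are nORFs matched to ≥ 1 DE transcript, inheriting its direction
(conflicting directions are reported as "both" and logged). The Fisher
check uses the sample odds ratio (a·d)/(b·c) and the two-tailed exact p
(sum of hypergeometric probabilities ≤ the observed table's).

**Sex QC.** Mean chrY expression per sample, plus single-linkage
clustering of XIST expression cut at two clusters; a sample is flagged
when its annotated sex disagrees with its cluster's majority. Constant
XIST degenerates gracefully (warning, no flags).

## HAR/TE association

Unique HARs are the overlap-merge of all source lists; each merged HAR
carries its members (source, id, conservation group) and the union of
their groups, so one unique HAR may count toward several of
vHAR/mHAR/pHAR. The ±100 kb association window is inclusive: a HAR whose
gap to the nORF span equals the window is associated. The 2 kb TE window
is strand-aware (5' of the span; a config switch gives strand-agnostic
left) and a TE touching the nORF itself is excluded. DE designation uses
the transcript's genomic span, introns included — features inside retained
introns count — with an exon-level mode behind a flag. The correlation
screen computes Pearson on values and Spearman as Pearson on average
ranks, both p values from the t transform with n−2 df (no exact
permutation; n ≥ 4 required); significance needs all four gates. The
pipeline inherits a TE's expression from its containing DE transcript;
TEs contained in no transcript simply yield no correlation pair.

## Loci and permutation enrichment

QC drops SNPs with HWE p < 1e-4 or MAF < 0.05 (strict comparisons; a SNP
at exactly MAF 0.05 survives). Stratification by association p produces
nested subsets. Clumping is greedy in ascending p (ties by position, then
rsid): an unassigned SNP with p < 1e-4 seeds a clump and absorbs all
unassigned SNPs within 3 Mb with r² ≥ 0.1; missing r² entries count as 0
and asymmetric entries are rejected. Among clumps whose index lies in the
MHC (hg19 chr6:28,477,797–33,448,354 by default), only the median-position
index survives; even counts take the lower median (the natural
tie-break for "most median"). A locus spans the index SNP and all SNPs
with r² > 0.5 (strict) within 250 kb; an isolated index gives a 1-base
locus.

Enrichment merges overlapping targets and overlapping reference nORFs
(sex-chromosome nORFs are excluded from the reference beforehand), counts
loci overlapping ≥ 1 merged target, and compares against n_perm = 5000
uniform same-size draws from the merged reference, with the +1 permutation
correction so p is never 0. The second round repeats the full procedure on
permuted target sets across every test in a family (strata × target set),
scores each replicate against the round-1 null, and corrects each observed
empirical p by the share of replicates whose family minimum is at least as
small; the corrected p is floored at the empirical p to preserve the
corrected ≥ empirical invariant under Monte-Carlo noise. Null sampling is
uniform over merged reference nORFs without length matching — the
reference tool's exact permutation scheme (SNP-density and gene-length
handling) is not reproducible from its description, so this scheme is the
package's own and is validated by calibration, not by equivalence.
Permutation p values are validly conservative and discrete; calibration
experiments therefore use geometries large enough (80 loci, 300 reference
nORFs) that the null statistic is fine-grained.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (seed, parameters); identical seeds
give byte-identical files. Defaults (the simulated study conditions):

- RNA-seq counts: negative binomial via gamma-Poisson mixing, dispersion
  0.2, log-link mean = baseline + diagnosis·lfc·ln2 + covariate effects +
  per-individual intercept N(0, 0.3); ~30% of individuals contribute two
  samples; cohort 40 CNT / 30 SCZ / 20 BD; 20% of transcripts DE per
  disorder with |log2 FC| uniform on [1, 2], random sign. Sex-linked
  features (male-only chrSY genes, female-high XIST) support the sex QC.
- Ribo-seq counts: canonical and non-canonical ORFs share a geometric grid
  of mean abundances (mean-matched so quantile bins hold both classes);
  nORF SD multipliers default to 0.5/2.0 (planted low/high noise), CV 0.3,
  50 samples.
- Features: planted HARs placed within the ±100 kb window of their nORF,
  planted TEs inside the 2 kb upstream window without touching the nORF,
  decoys far from every nORF; decoy group labels drawn from the curated
  unique-HAR composition (45.4/11.0/43.6% v/m/pHAR).
- GWAS: SNPs evenly spaced in LD blocks (within-block r² uniform on
  [0.6, 0.99], between-block 0, provided as a sparse table — clumping
  consumes only r², so no genotypes are simulated); p uniform except
  planted causal loci (−log10 p uniform on [5, 9]); 5% of SNPs get
  sub-threshold MAF and 2% failing HWE so QC has work to do.
- Two autosome-like chromosomes (chrS1/chrS2, 30 Mb) plus chrSY.

Not emulated: read-level sequencing noise, transcript-assembly artifacts,
batch structure and surrogate variables, LD decay within blocks,
population stratification, overlapping genes, and TE family-specific
expression. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under its stated model, not
robustness to the full messiness of consortium data.

## Problem sizes used in validation

Calibration and recovery experiments run at desk scale: 250 null
mixed-model fits (50 donors × 2 samples), 200 random-geometry enrichment
runs (300 reference nORFs, 80 loci, 300 permutations), 200 replicates of
effect recovery (100 donors × 2), DE recovery on 150 genes and 70 samples,
100 correlation-screen replicates (n = 60, ρ = 0.8), and 50 (25 in the
acceptance script) end-to-end scenarios of 40 genes, 1500 SNPs and 8
planted pHAR nORFs with 300–500 permutations per test.

## Known limitations

- The Wald t reference with residual df is approximate for unbalanced
  random-effects designs; LRT or Satterthwaite df are not provided.
- The round-2 corrected p is itself a Monte-Carlo estimate; with few tests
  it can sit at the empirical-p floor.
- Frame classification decides per transcript on the first shared codon;
  chimeric nORFs overlapping several CDSs in different frames report the
  in-frame call if any transcript matches.
- The expression inherited by TEs from containing transcripts conflates TE
  and host expression; locus-level TE quantification is out of scope.
- Unique-HAR counts and group fractions of the published seven-source
  compilation require those source interval lists as inputs; the package
  validates the merge machinery on synthetic multi-source fixtures.
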