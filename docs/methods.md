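# Methods

This note documents the models behind `splicelocus`, the defaults and why
they are set where they are, what the simulators do and do not emulate, and
the numerical choices a maintainer would want spelled out.

## The simulated locus

The default locus carries four biallelic variants whose minor alleles are
mutually exclusive on haplotypes — no chromosome carries two of them — with
population frequencies 8.8%, 3.4%, 0.06% and 2.2% and additive per-allele
effects on the lipid trait of −0.24, −0.13, +1.33 and −0.44 mmol/l
respectively. Exclusivity is enforced by construction: each chromosome
draws one outcome from a categorical distribution over {no minor allele,
minor allele of variant *i*} with the minor-allele frequencies as class
probabilities. Haplotypes are sampled i.i.d.: there is no background LD, no
recombination map and no relatedness. Relatedness enters the framework
only phenomenologically, through the genomic-control stage (see below);
genealogy-aware regression is out of scope and this is the package's main
known limitation relative to biobank-scale practice.

The quantitative trait is `mean + Σ β_v·count_v + covariate effects +
Gaussian residual`, with the residual scaled so the **marginal** SD equals
the configured `trait_sd` (default mean 4.00, SD 1.18 mmol/l, a serum
non-HDL-cholesterol distribution). Disease status is Bernoulli with
`logit P = log(baseline_odds) + Σ log(OR_v)·count_v`.

Imputed dosages shrink each haploid allele toward the population frequency:
`d = α·θ + (1−α)·p` with `α = √info`, so that the measured information
score `Var(d)/p(1−p)` equals the target exactly in expectation. This
reproduces the variance structure of imputation output without modelling
the imputation itself.

## The RNA-seq read model

One multi-exon plus-strand gene (default: 18 exons of 120 bp, introns of
250 bp, on its own contig). Per individual:

1. Each haplotype contributes transcript copies Poisson(`transcripts_per_unit`
   × weight), weight 1 for a wild-type haplotype and `mut_expr_ratio`
   (default **1.44**) for a haplotype carrying the index allele. The
   default is chosen so heterozygote total output is (1+1.44)/2 = 1.22× a
   non-carrier — a 22% expression increase.
2. A transcript from the index haplotype retains the designated intron
   (default index 14) with probability `retention_fraction_mut` (default
   **0.5**); others with `retention_fraction_background` (default 0).
3. Single-end reads (default 76 bp) are placed uniformly along each
   transcript, with per-transcript read counts proportional to transcript
   length, so per-base depth is proportional to copy number and the
   expected number of junction-covering reads per transcript is the same
   for spliced and retained templates. `depth` parametrizes the expected
   junction-covering reads per individual at baseline expression.
4. Phased exonic markers: measured individuals are heterozygous at each
   planted marker (mirroring a design that selects marker-heterozygous
   samples); the index haplotype carries the linked allele given by the
   marker's sign (default sign −1: the reference base). Reads are emitted
   as SAM with `N` CIGAR gaps across spliced-out introns; a read carrying
   any non-reference marker base is discarded with probability
   `map_bias_discard` (default **0.077**), which yields the observed
   non-carrier oriented-ASE baseline of 0.5/(0.5+0.5·0.923) ≈ 0.52.

What the generator does **not** emulate: paired-end fragments, base-quality
errors, positional coverage decay along transcripts, partial/alternative
splicing gaps, multi-mapping, or expression variation beyond Poisson copy
number. Passing tests therefore demonstrate correctness of the estimators
under this generative model, not robustness to those real-data artifacts.
One consequence worth noting: under uniform within-transcript coverage the
intron/exon coverage ratio of a half-retained transcript pool is ≈ 0.5,
whereas degraded real libraries can show much lower intronic coverage at
the same spliced-read proportion; the package reports both statistics and
treats the splice proportion as primary.

## Association and correction

Trait preparation averages repeated measurements per individual,
residualizes on covariates (categorical covariates dummy-coded; age with
first- and second-order terms), and applies the rank-based inverse-normal
transform r/(n+1) with midranks for ties. Effects are estimated by least
squares on dosage with conditioning variants as covariates; `beta_units =
beta_sd × trait_sd`. For log-scale traits (triglyceride-like), the natural
log is used and effects are reported as 100·(exp β − 1) percent change.
The logistic model reports the likelihood-ratio χ² and OR = exp β;
complete separation returns a flagged, estimate-free result.

Stepwise forward selection adds the smallest-conditional-P variant while
that P is below the threshold (default 5×10⁻⁸; the threshold is a
parameter, not a claim about the right genome-wide level), with ties broken
by position then id, and returns each selected variant conditioned on the
others. The scan is a vectorized residualization (QR of the selected set,
then per-candidate univariate fits), exactly equivalent to per-variant OLS.
Power note: at n = 50,000 a −0.13 mmol/l signal at MAF 3.4% on an SD-1.18
trait has noncentrality ≈ 40 against the 5×10⁻⁸ threshold, i.e. ~80%
selection probability per replicate — simulations at that size recover the
weakest of the four default signals in most but not ≥95% of replicates.

Genomic control estimates λ_g = median(χ²)/0.4549 (the χ²₁ median) and
divides χ² by max(λ_g, 1); deflation is never applied, so corrected P ≥
uncorrected P exactly when λ_g > 1. Variants with info < 0.8 are excluded
from scans by default. P values are tracked as log10 P internally so
underflow never produces zero.

## Meta-analysis

Cohort SEs are back-derived from printed β and two-sided P under the
normal approximation (se = |β|/Φ⁻¹(1−P/2); no t-correction, cohort dfs
being unknown), then combined with fixed-effect inverse-variance weights.
Heterogeneity is Cochran's Q against χ²_{k−1}. Because printed inputs are
rounded to 2 decimals, combined effects are reproducible to 2 decimals;
heterogeneity P values inherit more rounding noise and are reported, not
asserted.

## Splicing and ASE quantification

A read is *covering* if an aligned segment includes the last transcript-
orientation base of the upstream exon, and *spliced* only if its alignment
gap spans the full intron — both boundaries exact. Reads running into the
intron, or with partial/alternative gaps, count as covering-but-not-spliced.
A read whose final aligned base is exactly the junction base covers but
cannot show the splice; with 76 bp reads this depresses the proportion by
the factor 75/76 ≈ 0.987, visible in the simulated non-carrier median
(~0.99, not 1.00). CIGAR semantics: M/=/X consume read and reference, D
extends the covered reference span, N creates a gap, I/S consume read
only. Coordinates are 1-based inclusive at the surface (SAM/GFF3),
half-open 0-based internally; minus-strand models map "last base of exon
k" to the exon's genomic start.

Normalized coverage is reads-covering-base/(total aligned reads/10⁹), so
doubling the library size halves the value exactly. Exon summaries take
each individual's per-exon median, then the group median with the MAD as
spread. The expression shift test log-transforms per-individual region
medians, standardizes the pooled values to mean 0/SD 1, and compares
groups with an equal-variance two-sample t (equivalent to regression on
the group indicator); a pseudo-count of half the smallest positive value
handles zero medians.

ASE pools marker × individual oriented proportions within a genotype group
(per-individual aggregation is available as an option; under the default
simulation the two pooling rules agree to < 0.01). The group comparison is
Mann-Whitney, computed exactly (enumeration over assignments, valid with
midrank ties) when both groups have ≤ 8 observations and by the
tie-corrected normal approximation otherwise. The reported P carries the
simplifying assumption that pooled proportions are independent.

## Consequence prediction

The retained-intron mRNA is the exon sequence with the intron left in
place (reverse-complemented as a whole for minus-strand models). The last
intact codon is the last complete codon 5' of the intron insertion point;
translation proceeds through the intron in the shifted frame until the
first stop. The annotation `p.<Aa><Pos>fsTer<N>` names the last intact
residue and indexes the stop in the new frame, so "33 residues added"
prints as `fsTer34`; both numbers are exposed because published notation
is ambiguous between them. A premature stop more than 50 nt upstream of
the final exon-exon junction sets an advisory `nmd_predicted` flag that
never alters quantitative output. The bundled demo gene is constructed so
its retained intron yields exactly 33 novel residues and a truncation
(after residue 540) that removes the O-linked glycan, transmembrane and
cytoplasmic domains of the synthetic domain table.

## Problem sizes, seeds and determinism

All generators take explicit integer seeds; one seed per operation call;
identical config + seed reproduces every output bit-for-bit (the pipeline
report is hash-comparable). The reference experiments in
`splicelocus.study` use the study's group sizes (238 non-carriers, 15
heterozygotes, 3 homozygotes; n = 50,000 for the quantitative trait and
230,000 for disease) with junction depths of 2,000 reads (carrier splice
statistics), 50 (non-carrier splice statistic), 100 (ASE) and 150
(exon coverage) — deep enough that Monte-Carlo noise is well inside each
statistic's tolerance while a full run stays within a few minutes on one
CPU. Recovery of the −0.44 mmol/l and OR 0.76 effects has single-replicate
sampling SD of ~0.02 at these n; the test suite therefore averages five
replicates when asserting unbiasedness to 0.02.

## Known limitations

- No relatedness/kinship model; genomic control only.
- Single-transcript gene models; no isoform mixture beyond the binary
  retained/spliced split.
- Single-end reads; junction statistics depend only on per-read CIGAR, so
  paired-end support would change I/O, not estimands.
- The ASE mapping-bias model is a single discard probability, not an
  aligner simulation.
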