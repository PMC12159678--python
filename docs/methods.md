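# Methods

## The quantification problem

A provirus locus can host several transcription units whose exons
overlap almost completely: here a *long* form driven by a distal
cellular promoter, a *short* form driven by a solo-LTR promoter just
upstream of the provirus, and the mostly silent *canonical* form
initiated inside the 5′ LTR.  Reads from the shared exons are
uninformative about which unit produced them.  Rather than deconvolute
(EM over multimapping or shared regions), each transcript is counted
only over its **unique region** — the exonic bases covered by no other
model in the set — and the composite gene is counted over the
RepeatMasker provirus interval verbatim.  This trades a shorter
effective length (and hence higher TPM variance) for unbiased,
assumption-free attribution.

Interval arithmetic is exact on 0-based half-open integers; GTF I/O
converts to and from the 1-based inclusive convention, and book-ended
exons merge on parse.  Strand is carried but ignored by the subtraction
by default (the locus features are co-located); `same_strand_only`
enables stranded subtraction.  A unique-region rule that resolves to an
empty union is an error naming the feature, since counting over it
would silently return zeros.

## Read counting

Assignment mirrors featureCounts defaults: a read hits a feature when
any aligned block overlaps the feature's interval union by at least
`min_overlap_bases` (default 1); reads hitting two or more features are
discarded unless `allow_multioverlap`; non-unique alignments (NH > 1,
or mapq below `min_mapq = 30` when NH is absent) are excluded unless
the multimapper policy re-admits them.  Repeat loci make the
multimapping policy consequential, so it is explicit rather than
implied.  Mates of paired-end data are treated as independent
alignments; the simulator emits single-end reads because the counting
and junction logic, not fragment models, are under test.

TPM uses the standard rate normalisation over the full feature
annotation; per-sample totals are 10⁶ by construction and this is
asserted to 10⁻⁶ relative in tests.  Unknown chromosomes are tallied
and skipped, not fatal: a cohort BAM routinely contains contigs absent
from a locus annotation.

## Junction-read promoter scoring

The canonical promoter lies in the R region of the 5′ LTR, so
transcripts it initiates must cross the LTR / internal-region boundary.
A **junction read** has at least one block overlapping the LTR and at
least one block (possibly the same block, for contiguous read-through)
overlapping the internal region; either side may also be given as an
exon union.  Activity is presence/absence at a threshold of one read,
because observed junction capture is shallow (of the order of one read
per twenty million, CPM ≈ 0.05); the summary reports mean CPM over all
and over active samples.

## Contribution decomposition

The model is `a·long + b·short + c = gene` fitted by OLS with all three
TPM variables z-scored (sample sd, n−1).  The fitted coefficients then
act as normalisation factors on each sample's raw TPMs, and

    log_ratio = log2((a·TPM_long + ε) / (b·TPM_short + ε))

is the per-sample contribution statistic.  ε = 0.01 TPM guards zeros
(and, for degenerate fits, negative normalised values are floored at
zero before the guard so the ratio stays finite); samples under a fit
with a ≤ 0 or b ≤ 0 are flagged `degenerate`.

**Identifiability of the z-scale coefficients.**  Regressing a
*standardised* outcome on standardised predictors rescales the true
mixture weights by `1/sd(a*·z_l + b*·z_s + noise)`, which is not 1 in
general, so the z-scale pair (a, b) is identified only up to that
scale.  The ratio a/b — all the log-ratio statistic uses — is
unaffected.  The fit therefore also exposes the algebraically
equivalent original-scale OLS coefficients (`raw_coef_*`); on generated
cohorts, where the standardised mixture is mapped to TPM units with a
known factor (`gene_scale`), those invert exactly to the true mixing
weights (`estimated_mixing_weights`), which is how recovery is tested
(noiseless case to 1e-8; mean absolute error ≤ 0.02 at n = 500, noise
sd 0.1, over 100 seeds).

The decomposition is fitted on the pooled cohort by default — one pair
of normalisation factors applied to every patient — with `fit_on`
restricting the fit to a subset when per-cohort factors are wanted.

## Driver regression

Locus expression (z-scored) is regressed on a binary amplification
indicator (copy number ≥ 3; not z-scored, so its coefficient is a group
contrast in outcome-sd units) and z-scored pathway activity scores
(TNF receptor and IFN-γ signalling, consumed as inputs — ssGSEA is out
of scope).  p-values are two-sided from the t distribution.  An
all-amplified or none-amplified cohort drops the indicator with a
warning instead of failing.  Group comparisons use the pooled-variance
two-sided t test, paired t on differences, and Spearman correlation
with average-rank ties.

## LTR silencing evidence

Methylation: per-CpG calls (coverage, modified fraction; 5mC and 5hmC
summed upstream if separate) are summarised over the promoter region.
A site is covered at ≥ 5 reads and methylated at modified fraction
≥ 0.5; the region is methylated when ≥ 50% of covered sites are
methylated, indeterminate with no covered site.  These thresholds are
package decisions (the qualitative claim being operationalised is
"most sites methylated") and are configurable.  The coverage-weighted
mean is Σ(cov·frac)/Σcov over covered sites.  ± strand calls of one
CpG can be coverage-weight merged behind a flag; the default keeps
strands separate.

Consensus divergence: given an alignment of promoter-active reference
LTRs plus the query LTR, each column's reference consensus is the modal
non-gap base (ties broken alphabetically — deterministic) with
frequency = modal count / non-gap reference count; a divergence is
reported where the query's non-gap base differs and the frequency
reaches 0.8.  References are pre-filtered to ungapped length strictly
greater than 900 bp.  Alignment computation itself is upstream.

## Single-cell summaries

"Expressing" means raw count ≥ 1 (configurable); composition is the
cell-type breakdown of expressing cells (sums to 100%), per-type
expressing fractions are reported only for types with strictly more
than 600 cells, high/low stratification splits at 10 raw reads
(count ≥ 10 is high), and the per-patient percentage of cells in a
designated type set (e.g. tumor, AT2, fibroblast) is compared between
tumor and normal tissue with the Student t test.  Cell-type labels,
patient assignments and tissue are inputs; clustering and embedding are
out of scope.

## The synthetic generators

The generators define the conditions every closure test runs under.

- **Toy locus** (20 kb, single chromosome): long form with a 500 bp
  distal unique exon, short form with a 111 bp unique region, both
  splicing into the shared internal exon; canonical form reading
  through the LTR/internal boundary; repeat parts 5′ LTR (968 bp),
  internal (6032 bp), 3′ LTR (968 bp).  The geometry is relative only —
  real genome coordinates are inputs, not shipped.
- **Reads**: starts uniform on each spliced sequence, mapped to genomic
  blocks across junctions; exact splices, no error model; a configured
  fraction flagged non-unique (NH 2, mapq 0).  Expected counts are
  exact — every possible start is enumerated through the same
  assignment rule — so observed counts are Binomial(n, p) around them.
- **Cohort**: latent log-normal TPMs per group (tumor groups
  long-enriched, normal group short-dominant; squamous preset slightly
  above adenocarcinoma), amplification prevalence 0.10 in tumor groups,
  TNF/IFN covariates shifting the long/short latents; the composite
  gene is `location + scale·(a*·z_l + b*·z_s + noise)` with defaults
  a* = 0.7, b* = 0.3, noise sd 0.1, location 50, scale 10.  Group sizes
  150/150/100 are desk-scale stand-ins for cohorts of ~500/500/110.
- **Junction panel**: 114 samples, 11 active; an active sample is one
  whose promoter yielded at least one observable junction read, so
  active counts are 1 + Poisson(0.1) (mean ≈ 1.1 read, ≈ 0.05 CPM at
  the default 2×10⁷ library), inactive are zero — matching the
  shallow presence/absence regime the activity classifier targets.
- **Methylation**: coverage Poisson(30), modified calls
  Binomial(coverage, p); p = 0.8 in the methylated-promoter preset.
- **Cell matrix**: per-type tissue weights and per-feature
  (probability, mean extra count) with counts 1 + Poisson(mean) for
  expressing cells; the long form restricted to tumor (p = 0.107),
  fibroblast (0.0372) and AT2 (0.0108) cells, tumor cells present only
  in tumor tissue.
- **MSA**: references from a shared consensus with per-column noise
  0.02; the query equals the consensus except at planted substitutions
  (the consensus at a planted column is forced to differ — T where
  possible, reconstructing the T>C pattern).

What the generators deliberately omit — alignment error, fragment-length
and duplicate structure, batch effects, doublets, zero-inflation beyond
Bernoulli gating — bounds what passing tests show: they validate the
interval algebra, counting policies, estimators and thresholds under
the stated statistical model, not robustness to upstream artefacts of
real sequencing data.

## Numerical and design choices

- OLS via `numpy.linalg.lstsq`; agreement with a pseudo-inverse oracle
  asserted to 1e-10.  Perfect predictor collinearity (|r| > 1−1e-12) is
  an error.
- z-scores use the n−1 sd; constant vectors raise, naming the variable.
- Consensus ties break alphabetically; all generators are deterministic
  under their seed, and the pipeline report is byte-identical across
  runs with the same seed and config (JSON with sorted keys, no
  timestamps).
- Problem sizes in the test and acceptance runs (10⁴-read oracle
  comparisons, 100–200 replicate closures, 1000-simulation calibration)
  were chosen to hold Monte-Carlo error well below the asserted
  tolerances while keeping the default runs quick.

## Known limitations

- Unique-region counting discards shared-region information; loci whose
  transcripts have *no* unique bases cannot be quantified this way (the
  empty-union error makes this explicit).
- The decomposition assumes the composite signal is a linear mixture of
  exactly two forms; a third contributing unit biases a and b.
- The junction score cannot distinguish canonical-promoter transcripts
  from rare intron-retention read-through at the same boundary.
- Methylation summaries treat sites independently; no differential
  testing is provided.
- The pipeline is single-machine and in-memory; cohort-scale BAM
  processing is expected to happen upstream, with this package consuming
  the locus-restricted alignments.
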