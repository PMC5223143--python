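# Methods

`enhrev` re-implements, as one tested pipeline, the statistical analysis of
a four-group diet-perturbation study of liver gene regulation: animals fed
a control diet (Chow), a high-fat diet (HFD), and the two groups followed
through a subsequent weight-loss period (Chow-chow and HFD-chow).  The
scientific question the pipeline addresses is whether transcriptional and
enhancer-activity changes induced by the diet persist after weight loss.
Two contrasts carry all of the inference: the *diet* (DIO) contrast, HFD vs
Chow, and the *reversal* contrast, HFD-chow vs Chow-chow.

## Count model and differential testing

All sequencing readouts (exon reads, intron reads, acetylation-mark tags at
accessible regions, accessibility tags) are modeled as negative-binomial
counts with variance `var = mu + alpha * mu^2`.

**Size factors** are median-of-ratios: for features with all-positive
counts, each sample's factor is the median ratio of its counts to the
per-feature geometric mean.  Factors are identified only up to a common
constant; all downstream quantities depend on ratios of factors.

**Dispersion** is estimated per feature by the method of moments on
size-factor-normalized counts, pooling within-group variances over all
groups in the matrix: `alpha_hat = max(0, (var - mu) / mu^2)`.  A
mean-dispersion trend `a0 + a1/mu` is fitted by least squares over features
with `mu > 5`, and the final dispersion is `0.25 * alpha_hat +
0.75 * trend(mu)`, floored at 1e-8.  The weight matters: with 2-3
replicates per group the moment estimate is extremely noisy (4-8 degrees
of freedom), and weights near 0.5 leak enough of that noise into the Wald
denominator to inflate the p < 0.01 tail by 1.3-1.7x — and, because the
two contrasts share the dispersion estimate, to correlate their false
positives, which breaks the binomial false-overlap expectation used in the
persistence analysis.  At weight 0.25 the null tail is calibrated
(measured Pr[p < 0.01] ~ 0.010-0.013 against a known-dispersion floor of
0.009) while per-feature signal still contributes for genuinely
high-dispersion features.

**The Wald test** compares two groups on normalized group means with a
pseudocount of 0.5 (so zero counts never give infinite fold changes).  The
standard error of `log2fc` comes from the delta method under the NB
variance model; the statistic is referred to the standard normal, and BH
FDR is computed over all features with any count in the contrast samples.
`log2fc` is computed as `log2(m_b) - log2(m_a)` so that exchanging the
contrast direction negates it exactly.  This is deliberately a two-group
estimator, not a GLM: every comparison in the supported design is
pairwise, and the closed-form estimator is transparent and directly
checkable against simulation.

## Nascent transcription

Introns are spliced out co-transcriptionally, so intron-mapping reads
measure transcription at the time of sampling while exon reads measure
accumulated mRNA.  Genes are called regulated from the exon-level test
(default FDR < 0.01 and fold change >= 1.5) and then classified as
regulated by *ongoing transcription* at intron-FDR threshold `t` (grid
{0.01, 0.05, 0.1}) when the intron-level FDR is below `t` **and** the
intron fold change has the same sign as the exon fold change.  The sign
requirement prevents counting discordant intron noise as ongoing
regulation.  Gene models are single-isoform (sorted disjoint exons; introns
are the gaps); multi-isoform ambiguity is out of scope.

## Peak calling

Accessible regions are called from single-bp tag tracks with a sliding
window scan (default 200 bp windows, 100 bp step).  Window counts are
tested against a single genome-wide uniform Poisson rate (total tags /
effective span, where span sums the maximum tag coordinate per
chromosome); windows passing BH-FDR < 0.001 **and** a tag-density floor of
35 tags are merged into maximal peaks scored by their best window.  A
global background (rather than local lambda or a control track) is
adequate for the synthetic tracks this package targets; it will over-call
in genomes with strong large-scale coverage bias.

## Enhancer-gene proximity enrichment

For a region class (induced or reduced acetylation) and a gene set, the
statistic is qualifying region-gene pairs per gene, where a region
qualifies if any bp lies within 100 kb of the gene's TSS.  The null is
resampled gene sets: 4 rounds of 200 genes drawn uniformly without
replacement from the annotated genes excluding the test set (excluding
them avoids contaminating the null with true signal).  The p-value is a
two-tailed one-sample t-test of the round values against the observed
value; with n = 4 rounds this test is intentionally low-powered — it is
reported as-is rather than "fixed", because the round count is part of the
emulated analysis.  The fraction of test genes with at least one
qualifying region is reported alongside.

## Persistence classification

Each region in the accessible universe is classified by crossing the two
contrasts at the lenient screen p < 0.01: *putative persistent* (both
contrasts significant with concordant sign), *reversible* (diet contrast
only), *weight-loss-specific* (reversal contrast only), *unregulated*
(neither).  Venn overlap counts are reported at FDR < 0.1 and at p < 0.01.
Under a fully reversible truth, putative-persistent calls arise only from
false overlap, expected `Binomial(|diet set|, p_cut * 0.5)`; the
diagnostics quantify this by summarizing, per class, z-scored normalized
counts per group and the empirical FDR distributions of both contrasts —
noise-driven persistent calls carry weak (high) reversal FDR, genuinely
persistent ones carry strong (low) reversal FDR.

## Motif statistics

Motif strength of a sequence is the best log2-odds PWM score over all
offsets and both strands, with probabilities floored at 1e-3 before
log-odds (no infinite penalties) and `N` bases scoring zero.  Occurrence
enrichment between sequence sets thresholds the best score and applies a
hypergeometric tail on pooled hits — a deliberate simplification of
ZOOPS-style motif enrichment, appropriate because the synthetic sequences
have controlled (i.i.d. uniform) composition.  Strength comparison across
sets reports quartiles and two-sided Wilcoxon rank-sum p-values (scores
are bounded and non-normal, so a t-test would be wrong in the tails).

## The synthetic study generator

The generator produces the complete study a real experiment would deposit:
gene models and accessible regions on one synthetic 50 Mb chromosome, NB
count matrices for exon/intron RNA (3 replicates per group), the
acetylation mark (3 per group) and accessibility (2 per group), region
sequences with planted motifs, a sample sheet, and per-feature ground
truth.  Defaults encode the emulated study's structure:

- **Effect classes.** 2% of genes each: up/down transcriptional (exon and
  intron shifted) and up/down turnover-only (exon shifted only); regions:
  4% induced vs 2% reduced acetylation (the observed asymmetry toward
  induction); persistent and weight-loss-only classes default to 0 — the
  fully-reversible scenario.  Effect size log2FC = 1.5.
- **Counts.** NB dispersion 0.05; per-feature base means log-normal around
  200 (exon), 100 (intron), 150 (mark and accessibility) counts;
  per-sample size factors log-uniform on [0.7, 1.4].
- **Accessibility is class-independent** by default: open chromatin does
  not change with diet; only the activity mark at pre-established regions
  does.  A config switch can plant accessibility effects for power
  studies.
- **Coupling.** 80% of induced/reduced regions are placed within 100 kb of
  the TSS of a same-direction regulated gene (the linked gene is recorded
  in the truth table).
- **Motifs.** A synthetic 10-bp PWM (95% consensus probability per column)
  is planted centered in 70% of induced-region sequences.
- **Layout.** Gene TSSs occupy distinct 10 kb slots (3000 genes need more
  than the naive 20 kb slots a 50 Mb chromosome could hold); regions
  occupy 1 kb slots, except coupled regions, which are placed inside their
  gene's window with overlap rejection.  Genes are 4 exons of 300 bp with
  2 kb introns.

Everything derives from one seeded `numpy` generator, so a seed reproduces
the bundle bit-for-bit, and the written bundle (TSV/BED/FASTA/TOML)
round-trips losslessly.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: GC and mappability bias, multi-isoform
genes and ambiguous read assignment, batch effects, local background
structure in tag tracks, realistic genome sequence composition,
heterogeneous per-feature dispersions, and fragment-level (paired-read)
counting.  Results on this generator validate the statistical machinery,
not robustness to those artifacts.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open throughout; tags are single-bp 5'
  positions; a tag overlapping k regions counts in all k.
- All-zero features get missing p/FDR and are excluded from the BH `m`.
- Constant rows z-score to zeros (flagged) rather than NaN.
- PCA component signs are fixed (largest-magnitude loading positive) so
  scores are deterministic; the transform is log2(normalized + 1).
- PWM scan ties break toward the smallest position, forward strand.
- Proximity enrichment with an empty region set reports a missing ratio
  rather than zero (0/0 is undefined, not "no enrichment").
- Summary JSON is written with sorted keys; a fixed seed reproduces it
  byte-for-byte.

## Problem sizes

The validation suite runs the generator at its default size (3000 genes,
8000 regions, 12-50 Mb synthetic chromosome) for single-run checks, 20
independent default-size studies for the false-overlap expectation, and
5000-feature matrices for calibration/recovery checks; the full pipeline
run completes in a few seconds, the whole suite in well under a minute of
compute.  These sizes give the binomial/recovery assertions comfortable
margins while keeping runs cheap to repeat.

## Known limitations

- The Wald tail remains mildly anticonservative (~1.3x at p ~ 1e-3) at
  2-3 replicates; empirical FDR at BH 0.1 is correspondingly ~0.13 rather
  than 0.10 in recovery simulations.  Exact tests or a GLM with
  higher-order corrections would tighten this at the cost of opacity.
- The peak caller's global Poisson background is not suitable for real
  genomes with copy-number or accessibility-density structure.
- The proximity null resamples genes, not regions; it answers "are these
  genes unusually near regulated regions", not the converse.
- No independent filtering or outlier moderation in the differential
  tests; results for very-low-count features rely on the pseudocount.
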