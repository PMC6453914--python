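# Methods

## Problem and model

`hybmode` analyses how gene expression is inherited in F1 hybrids of two
chicken breeds — Cornish (Cor, a broiler) and White Leghorn (WL, a layer)
— from a reciprocal-cross RNA-seq design. Pure-bred offspring groups CC
(Cor x Cor) and CW (WL x WL) stand in for the parents; CL (Cor male x WL
female) and LC (WL male x Cor female) are the reciprocal hybrids. Samples
are grouped by sex into four analysis groups, each binding one parental
pair and one hybrid unit:

| group | Cor unit | WL unit | hybrid unit |
|-------|----------|---------|-------------|
| MC    | Cor♂     | WL♂     | CL♂         |
| FC    | Cor♀     | WL♀     | CL♀         |
| MR    | Cor♂     | WL♂     | LC♂         |
| FR    | Cor♀     | WL♀     | LC♀         |

For each gene and group, the hybrid's percent expression *h* is compared
with the parental values *p*<sub>Cor</sub> and *p*<sub>WL</sub> using the
symmetric fold ratio `max(a,b)/min(a,b)`. Values are *similar* when the
ratio is strictly below a threshold *t* = 1.25 (the boundary counts as
dissimilar; `boundary_similar=True` flips this). The mode assignment is:

- similar to both parents → **conserved**
- similar to exactly one parent → **Cor-dominant** / **WL-dominant**
- similar to neither, strictly between the parents → **additive**
- above both → **over-dominant**; below both → **under-dominant**
- all three values zero → `unclassified_zero`, excluded from counts

The symmetric linear ratio is equivalent to a |log fold| ≥ log 1.25 cut on
log-transformed percentages, with log base (2) used only for reporting; it
avoids log-of-zero. A hybrid similar to both parents is conserved even if
the parents differ from each other by more than 1.25-fold: the definition
references only hybrid-parent contrasts. "Between" is strict; equality
with a parental value is unreachable in the additive branch because it
would have been similar to that parent.

## Normalization and filtering

Mapped read counts are averaged over replicates per (cross, sex) group,
then total-count scaled to a percent of the group's summed mean counts, so
each group column sums to 100. This removes depth differences between
libraries; it is invariant to rescaling any group's counts. Filtering
happens first — genes on the Z chromosome (chicken dosage compensation is
incomplete, so ZZ males exceed ZW females) and genes with zero counts in
every sample of a tissue are removed — so that every group shares one
denominator over the retained gene set. Whether the original analysis
computed its denominator before or after filtering is not documented; the
post-filter denominator is this package's choice and keeps the
normalization identity `filter ∘ normalize = normalize ∘ filter` trivially
true.

## Pseudo-genome construction

Breed-diagnostic SNPs are depth-filtered — retained only if supported by
strictly more than 10 reads in *each* breed, relaxed to strictly more than
4 reads on the Z chromosome — and substituted into the reference sequence
to give per-breed pseudo-genomes (toy scale: read alignment and SNP
calling are upstream of this package). Only biallelic SNVs are
substituted; indels and multi-allelic records are skipped with a logged
warning. When genotypes are available, heterozygous sites are skipped for
a breed (a single sequence cannot carry two alleles). Substitution
validates the reference base at each site by default, which also makes
accidental double-substitution fail loudly. VCF positions are 1-based;
internal indexing is 0-based.

## Allele-specific expression of dominant genes

Dominant genes are split by parental direction (Cor > WL vs Cor < WL) so
that opposite-signed ratios cannot cancel, then two unweighted OLS fits of
log2(WL-side) on log2(Cor-side) are computed: one on parental percent
expression, one on hybrid allele expression. The Pearson correlation
between the parental log-ratio and the allelic log-ratio, with its
p-value, quantifies cis-regulatory signal. Genes with a zero on any
required side are excluded from log-scale fits rather than pseudocounted
(the exclusion count is logged); fewer than three usable genes is an
error. Log base 2 throughout.

**Coverage filter.** Low-coverage genes are removed before regression
using a normalized-read floor of 10. The floor is applied after
total-count scaling of each hybrid unit's allele totals to the mean unit
depth (`scaling="depth"`), so "10 normalized reads" is a depth-equalized
coverage requirement. A percent-of-total variant (`scaling="percent"`) is
available, but on a percent scale no gene in a realistic library reaches
10 (that would be 10% of all mapped reads), so a fixed floor of 10 is only
meaningful on a count-like scale; the depth-equalizing form is therefore
the default.

## Consolidation and category statistics

Across the four groups a gene is *consistent* when all four modes agree;
independently, a majority rule assigns a gene the mode it shows in two or
more groups. A 2-2 tie between two modes is labelled `ambiguous` and
excluded from per-mode gene lists; fewer than two agreeing groups gives
`none`. `unclassified_zero` calls count as absent. Four-way Venn region
counts are computed exactly by membership enumeration.

Category counts are compared at the only granularity the group tables
provide — four per-group observations per tissue per category: a
Kruskal-Wallis test across tissues on mis-expressed (over- +
under-dominant) counts, and within each tissue a two-sided Mann-Whitney U
between Cor-dominant and WL-dominant counts (exact p-values at these
sample sizes when untied). Divergence summaries convert
detected/up/down-regulated gene counts into percentages rounded to two
decimals per direction and one decimal for the combined fraction.
Differential-expression calling itself is out of scope: the summary
consumes externally produced counts, and the reported count tables of the
WL x Cor day-old-chick experiment ship in `hybmode.published` as worked
example inputs.

## Synthetic data generator

The generator emulates the study design at the count level: ~15,000 genes
(defaults; all sizes configurable), four crosses x two sexes x three
replicates, negative-binomial counts with a gene-shared dispersion
(variance m + m²/k) around expected abundances scaled to a common library
size. Per-gene baselines are log-normal (log2 sd 1.5). Each gene draws a
true mode from a configurable mixture (default roughly brain-like: 55%
conserved, 5% additive, 14%/10% Cor/WL-dominant, 8%/8% over/under);
expected abundances are constructed to satisfy the mode definitions with
safety margins — dissimilar hybrid-parent contrasts at least 1.5-fold,
similar contrasts at most 1.1-fold — keeping true effects away from the
1.25 decision boundary so recovery is well-posed. The additive hybrid sits
at the arithmetic mid-parent, which forces the parents of additive genes
at least 3-fold apart for the 1.5 margin; dominant-gene parental
divergence is drawn around 1.6-2.5-fold, consistent with mostly subtle
(<2-fold) divergence between these breeds. A configurable fraction of
genes is Z-linked (4%) or entirely silent (2%).

Allele-specific counts: each gene draws a Poisson number of informative
SNPs (mean 2.5; zero-SNP genes yield no ASE rows); per hybrid unit, an
`ase_capture` fraction (25%) of the gene's summed reads is
allele-assignable, and the Cor-allele count is binomial with success
probability `cis/(1+cis)`. Dominant genes are cis-driven with probability
`cis_fraction` (default 0.5), in which case the cis-ratio equals the
parental ratio; all other genes have cis-ratio 1 (trans-like). A single
master seed drives stage-keyed generators, so identical configurations
reproduce outputs bit-exactly.

What the generator does **not** emulate: mapping bias, SNP-calling error,
overdispersion heterogeneity across genes, sex- or parent-of-origin
effects, correlated gene modules, or partial cis/trans mixtures within a
gene. Passing recovery tests therefore demonstrates correctness of the
classification and regression machinery under the stated count model, not
robustness to those real-data artefacts.

## Problem sizes and numerical choices

Recovery checks use 10,000 genes with deep libraries (2x10⁷ expected
reads) and near-Poisson dispersion (k = 10⁴), giving group-mean
coefficients of variation well under 5% so that ≥99% true-mode recovery
is the expected behaviour; the pure-cis ASE regime check uses full allele
capture at 10⁸ reads so binomial ratio noise is negligible and the
parental/allelic ratio correlation approaches 1. The end-to-end example
pipeline uses smaller gene counts purely as a demonstration scale.
Ratios of zeros: `fold_ratio(0,0)=1` (similar), one-sided zero is +inf
(dissimilar). Rank tests fall back from exact to tie-corrected
asymptotics only when ties occur. OLS is unweighted; regression results
carry n and the dropped-zero count.

## Known limitations

- The 1.25-fold rule is a hard threshold; genes near the boundary flip
  modes under small noise. An FDR-style similarity test is deliberately
  not the default (the threshold rule is the analysis being reproduced).
- Consolidation ties and `none` assignments depend on how many groups a
  gene is classifiable in; tissues are processed independently.
- The ASE regression treats summed SNP counts per gene as one
  observation; SNP-level variation within a gene is not modelled.
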