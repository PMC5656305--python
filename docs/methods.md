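# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data tests do and do not show
about real data.

## Replicate concordance

Candidate binding regions are the merged union of both replicates' peak
calls. Merging joins overlapping *and* book-ended intervals ([a,b) + [b,c) →
[a,c)): two peak callers disagreeing by a single base should not produce two
regions. Reads are represented by their 5′ coordinate; a read is counted into
a region when that coordinate lies in the half-open interval, so each read
contributes to at most one (disjoint) region.

Library-size normalization rescales each replicate's counts to the *mean* of
the two library sizes rather than to counts-per-million. This keeps values on
a reads-like scale so the read-count threshold (mean > 100) retains its
literal meaning.

The filter keeps a region iff mean > 100 and ratio < 2, both strict, where
ratio = max/min of the two normalized counts. A region with one zero count
has ratio +∞ and is rejected (`high_ratio`); with both zero the ratio is
undefined and the region is rejected as `low_mean` — a region with no reads
in a replicate cannot be concordant. Kept + rejected always partitions the
input, and every rejected region carries at least one QC flag.

Cluster QC replaces a manual genome-browser inspection with a reproducible
rule: k-means (fixed seed, 10 restarts, log1p-transformed profiles) on binned
read intensity around each region midpoint, flagging any cluster whose mean
centre-bin intensity falls below 25% of the global mean centre-bin intensity.
The 25% fraction is a configurable default chosen to separate "very few reads
around the centre" from ordinary signal variation.

An optional chromosome exclusion list (for unplaced/mitochondrial scaffolds
in real genomes) defaults to empty because synthetic genomes have none.

## Feature assignment and enrichment

A peak is assigned by its midpoint — unambiguous for wide peaks and
equivalent to distance-to-TSS annotation logic. Precedence: promoter
(closed window, ±1000 bp of a TSS), then transcription-termination window
(±1000 bp of a TES), then gene body, else intergenic. With TSS/TES-only
annotation the exon/intron/UTR distinctions are not resolvable and collapse
into `gene_body`. Nearest-TSS ties break toward the lexicographically
smaller gene id, deterministically. The signed TSS distance is
transcription-oriented (negative = upstream).

Enrichment compares the peaks' category fractions against random positions
that are *width-matched* (widths resampled from the observed peaks) and
placed uniformly with chromosomes weighted by length. Width-matching keeps
the null unbiased for category fractions; single-base random positions would
slightly distort the window-overlap geometry for wide peaks. A category with
zero random mass reports +∞ with a warning rather than failing.

TSS metaprofiles bin reads in [tss − w/2, tss + w/2) in 50-bp bins, flip
minus-strand genes so bins run upstream→downstream (the oriented window for
a minus gene is (tss − w/2, tss + w/2] in genomic coordinates, which maps
exactly onto the same bin grid), average over genes and scale per million
total reads. The window size is an explicit parameter (2 kb in the tests);
there is no hidden default behavior beyond that argument.

## Differential expression

The DE stage is a deliberately minimal two-group NB procedure, not a GLM
package, and claims no numerical equivalence with one:

- **Background filter.** A gene is excluded iff its total raw count across
  all samples of the contrast is strictly below 10 ("less than 10 reads" is
  read as a total, the natural reading for a per-experiment expression
  filter).
- **Size factors** by median-of-ratios against the geometric-mean reference.
- **Dispersion** per gene by method of moments on normalized counts,
  d = (var − μ)/μ², floored at 1e-8, then averaged 50/50 with a fitted
  mean-dispersion trend d(μ) = a₀ + a₁/μ. With thousands of genes the trend
  absorbs most of the gene-wise estimator's noise.
- **Wald test.** log2 fold change from group means of normalized counts
  (each group mean floored at 0.5 — a half-count — so the log stays defined
  for all-zero groups); its variance from the NB law var = μ/s + dμ² per
  sample, delta-method to the log scale; standard normal reference; BH
  adjustment across tested genes.
- **Status.** up iff padj < 0.05 and 2^lfc > 1.5; down iff padj < 0.05 and
  2^lfc < 2/3; else ns. The fold threshold is applied two-sided on
  unshrunken estimates and is a configuration value.

Measured operating characteristics on synthetic data (3 vs 3 replicates,
d = 0.05): raw-p type-I error ≈ 0.06–0.07 at nominal 0.05 over 20,000 null
genes; sensitivity > 0.95 with observed FDR < 0.1 for 4-fold planted
effects. These are properties under the generator's NB world — real data
add outlier counts, batch structure and mean-varying dispersion that this
stage does not model.

Sample QC uses log2(normalized + 1) — a documented stand-in for a variance
stabilizing transform — with Euclidean distances, Pearson correlations and
average-linkage ordering. With a single gene the correlation is undefined
and omitted with a warning.

## Overlap statistics

The overlap test is the exact hypergeometric upper tail P(X ≥ k) (scipy's
log-gamma survival function), with expected overlap Kn/N, fold k/(Kn/N) and
the Venn triple. Enrichment is the default direction; depletion is a flag.
The universe is always an explicit argument, never inferred — different
questions legitimately use different universes, and silently guessing one is
the classic error of web enrichment tools. Query genes absent from the
universe are added to it with a warning (lenient mode, matching common
web-tool behavior) or rejected with the offending ids (strict mode).

Target classification: for an activator, *potentially direct* = DE genes
with binding evidence that go down on its loss; for a repressor, evidence
plus up. All other DE genes are *potentially indirect*; the two classes
partition the factor's DE genes. "Evidence" defaults to promoter-window
binding assignments.

The directional breakdown of shared DE genes is a 2×2 table (direction in A
× direction in B) whose cells always sum to the shared total. The spec-style
"per-cell" enrichment is reported as per-cell observed/expected fold from
the margins; the independence test itself is a single two-sided Fisher exact
p — for a 2×2 table that p is a table-level quantity, not a per-cell one.

## Courtship statistics

LI = (C̄I_naive − C̄I_trained)/C̄I_naive from group means; it is scale-free
and may be negative. Mann-Whitney uses exact enumeration when the combined
n ≤ 12 without ties, otherwise the normal approximation with mid-ranks, tie
correction and continuity correction; the method used is reported.

The between-genotype test is a bootstrap randomization test: under the null
the genotypes share one CI distribution per condition, so naive CIs are
pooled across genotypes, trained CIs likewise, and each of B replicates
resamples with replacement groups of the original per-genotype-per-condition
sizes and recomputes ΔLI. The two-sided p is (1 + #{|ΔLI*| ≥ |ΔLI_obs|}) /
(1 + B), never exactly zero. Pooling within condition preserves the
naive/trained structure that the LI ratio needs; a label-permutation variant
is available behind `scheme="permutation"`. The published description of
this procedure does not pin down the resampling scheme or sidedness, so this
choice is documented and configurable rather than asserted as the original.
Measured calibration: null rejection ≈ 0.05–0.06 at nominal 0.05; power ≈ 1
at a true ΔLI of 0.6 with 50 flies per group and beta concentration 20.

## qPCR

ΔΔCt with multiple reference genes combines references by the arithmetic
mean of their mean Cts — the geometric mean on the expression scale, the
standard choice when the combination rule is unstated. Fold =
2^(−ΔΔCt); the control condition maps to exactly 1, and adding a constant to
every Ct leaves all outputs unchanged. ChIP-qPCR enrichment is
%input(positive) / mean(%input of the two negative regions); percent input
corrects the input Ct by log2(100/input_percent), with the input fraction an
explicit configuration value.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions used throughout the tests:

- **Genome**: equal-length chromosomes, non-overlapping 2–8 kb gene bodies
  placed by stick-breaking, random strands. No isoforms, no overlapping or
  nested genes, uniform intergenic structure.
- **Peaks** (defaults: true mean depth 500 reads/region, NB dispersion 0.05,
  low-signal mean 20, discordant ratio 3): true promoter peaks centred
  within ±500 bp of distinct TSSs, distal/spurious regions on a 5-kb grid
  ≥ 2 kb from any TSS, ~500-bp regions, replicate boundaries jittered ±20 bp
  so merging is exercised. Discordant regions alternate which replicate is
  inflated so the two simulated libraries stay depth-matched, as real
  depth-matched libraries are. Read positions are single 5′ coordinates
  drawn uniformly within their region — no fragment-length model, no
  mappability or GC bias.
- **Counts**: NB with var = μ + dμ² (d = 0.05, matching typical bulk RNA-seq
  biological replicates), lognormal baseline means around 200, DE genes
  shifted by exactly 2^lfc, a configurable fraction of genes forced below
  the 10-read background threshold, and a controlled shared-DE fraction
  across the two contrasts with directions assigned independently (the
  observed direction pattern in such studies is close to unstructured).
  Exactly ⌊de_fraction·n⌋ genes are DE per contrast and ⌊shared·n⌋ shared —
  gene assignment is deterministic; only expression values are random.
- **Courtship**: CIs drawn from Beta(mean·c, (1−mean)·c) with concentration
  c = 20 (SD ≈ 0.10 at mean 0.7, in the range of real courtship assays);
  defaults use naive mean 0.7 and group sizes in the upper-50s to low-60s,
  the scale of a real conditioning experiment.

Passing tests therefore demonstrate correct arithmetic and sane operating
characteristics under an idealized NB/beta world; they do not demonstrate
robustness to alignment artifacts, batch effects, peak-caller idiosyncrasies
or non-NB count noise.

Problem sizes used by the test suite and the acceptance script — 200-gene
genomes, 250 simulated peak regions, 5,000–20,000-gene count matrices, 1000
null behavioral datasets of 120 flies with 1000 bootstrap replicates each —
were chosen as the smallest sizes at which the measured rates have
comfortably small Monte-Carlo error.

## Numerical and degenerate-input decisions

- Coordinates are 0-based half-open everywhere internally; 1-based
  annotation input is converted at the reader via a flag.
- All randomness flows through explicit integer seeds; no function reads
  ambient random state.
- Hypergeometric tails use scipy's survival function (log-gamma arithmetic);
  the test suite verifies all instances with N ≤ 25 against exact integer
  enumeration (max relative error ~6e-16).
- concordance ratio with one zero count is +∞; with two, undefined and
  flagged. K-means requires k ≤ number of peaks. Empty peak sets propagate
  as empty tables, not errors, except where a statistic becomes undefined
  (enrichment of zero peaks, LI with zero naive mean), which raise.
- Randomization replicates that produce a zero resampled naive mean (and
  hence an undefined LI) are dropped from the null distribution; the p-value
  denominator counts only finite replicates.
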