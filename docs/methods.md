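# Methods

## Screen model and scoring

A GO-CRISPR screen consists of one sequenced library pool (L0) and two cell
populations — Cas9-positive and Cas9-negative — transduced with the same
pooled sgRNA library in independent infection events, each sampled in n ≥ 2
replicates at an initial (T0) and final (Tf) timepoint, with the selective
pressure applied between them. The default design is the 13-sample layout:
L0 plus 2 populations × 2 timepoints × 3 replicates. Replicate i at T0
pairs with replicate i at Tf.

Counts are incremented by a pseudocount (default 1) so no abundance is
zero, then normalized by DESeq-style median-of-ratios: the reference for
sgRNA i is the geometric mean of its counts across all samples, sample j's
size factor is the median over i of count_ij / reference_i, and abundances
are counts divided by the size factor. This absorbs per-sample sequencing
depth; multiplying any one sample's counts by a constant rescales all
abundances by a single common factor and therefore changes no fold change,
rank, or downstream score (exactly so on zero-free matrices; the additive
pseudocount breaks exactness only on zero counts).

Per gene j and replicate r, the Gene Score is
GS_jr = Σ over the gene's detected sgRNAs of log2(abundance_ir /
mean reference abundance_i). The reference is the arithmetic mean of
normalized abundances over the contrast's denominator samples (the single
L0 sample for the library contrast). A guide counts as *detected* when its
**raw** (pre-pseudocount) count is ≥ 1 in at least one sample of the
contrast (numerator ∪ denominator); detection on raw counts stops the
universal pseudocount from declaring every guide observed. Undetected
guides contribute nothing to GS; s_j is the number detected.

Within each (replicate, contrast), Gene Scores are ranked ascending (rank 1
= most depleted) with average ranks on ties, so the result is invariant to
input order; rank sums are verified to equal x(x+1)/2. The Enrichment Score
is ES_j = (mean rank across replicates) / s_j, computed independently for
the library, initial, and final contrasts, and the Enrichment Ratio is
ER_j = log2(Final ES_j / Initial ES_j).

Significance: a paired two-sided t-test (df = n − 1) across replicates,
pairing replicate i's initial-contrast statistic with its final-contrast
statistic. The paired quantity is the per-replicate scaled rank
(rank_jr / s_j), i.e. exactly the replicate-level contribution to the ES
that the ER aggregates; pairing raw Gene Scores instead is available via
`TracsParams(pair_statistic="gene_score")`. Benjamini–Hochberg step-up
adjustment controls the FDR at the user level (default 10%); the final
essentiality filter separately applies Library ES > cutoff, ER < 0 and
p_adj < 0.05, all strict inequalities, mirroring the method's dual use of
an FDR control level and a fixed p_adj threshold.

The Library ES cutoff is the first quartile (configurable q) of Library ES
over scored genes, with linear interpolation between order statistics.
Genes below it had their guides underrepresented in the Cas9-negative
population before any editing was possible; their Initial/Final scores sit
at rank extremes driven by tiny denominators and are excluded from the
essential list.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| pseudocount | 1 count | added to every raw count before normalization |
| library_quantile | 0.25 | Library ES quantile flagged unreliable |
| fdr_level | 0.10 | BH control level for the `significant` flag |
| er_max / padj_max | 0 / 0.05 | strict thresholds of the essential filter |
| pair_statistic | scaled_rank | quantity paired in the t-test |
| s_mode | detected | ES divisor: detected or library-design guide count |

The s divisor follows the method's stated formula (divide by the detected
guide count); note that a smaller s *raises* ES, so the "penalty" for
undetected guides acts through the gene's guides contributing fewer
log-fold-change terms, not through the divisor. `s_mode="library"` divides
by the designed guide count instead for users who prefer a fixed divisor.

## Degenerate inputs and numerical choices

- Genes with no detected guide in **any** contrast are excluded globally and
  flagged, so all three rankings share one gene universe and ES values are
  comparable across contrasts.
- Zero-variance paired differences give p = 1 with a `constant_difference`
  flag rather than NaN, keeping BH well defined.
- A single-sample matrix passes through normalization with size factor 1
  and a warning.
- Guide counting is exact, case-insensitive, at a fixed offset or after a
  5' anchor; duplicate spacers in a library are rejected at matcher
  construction because assignment would be ambiguous. Reads are checked on
  the forward strand, optionally also as reverse complement.
- Result tables are written with shortest-round-trip float formatting; two
  runs on identical input are byte-identical.

## The simulator

`simulate_screen` draws, per guide: (1) library representation ~
log-normal(0, σ) with σ = 0.8 by default, matching the skew of a pooled
library; (2) with probability `dropout_prob` (default 0.05) per population,
a Cas9-independent stochastic loss event that multiplies the guide's
representation by a severe bottleneck factor 10^U(−3,−1) — independent
draws for the two populations, same probability, because the loss has
nothing to do with editing; (3) T0 abundance = surviving representation,
identical at Tf for Cas9-negative cells; (4) in Cas9-positive cells, guides
of essential genes are divided by `depletion_effect` (default 10) at Tf
with per-guide probability `editing_efficiency` (default 0.9); (5) observed
counts are negative-binomial draws (variance μ + αμ², α = 0.1 by default;
α = 0 degenerates to Poisson) around depth-scaled abundances with the
sample total fixed at `mean_depth` × number of guides, independent per
replicate. Non-targeting controls are single-guide pseudo-genes named
`NTC_####` and never depleted. Default scale is 2,000 genes × 6 guides +
100 NTCs at 500× depth — a genome-wide screen's structure at desk scale.

The loss event is modeled as a severe bottleneck rather than an exact zero
deliberately: a guide whose count is exactly zero in every sample of a
population yields, after the pseudocount, *constant* signals across
replicates and timepoints — rank-stable scores and degenerate p = 1 genes —
which is not how partially lost guides behave in real data. Bottlenecked
survival (0.1–10% of representation) keeps lost guides in the noisy
low-count regime where they genuinely confound scoring, which is the
phenomenon the Library ES filter exists to remove; the simulator
demonstrates this directionally (raising `dropout_prob` concentrates
extreme Initial/Final ES among low-Library-ES genes).

What the simulator does **not** model: multiplicity-of-infection
distributions and multi-guide cells, per-cell lineage drift (editing is a
population-level Bernoulli per guide), PCR amplification bias, sequencing
error in the spacer (counting in the simulator round trip is exact), and
any biology of the selective pressure. Passing tests on simulated screens
therefore validate the scoring arithmetic and its statistical behaviour
under the stated generative assumptions, not performance on any real
screen.

## Evaluation

ROC curves treat higher score = more positive; for essentiality the score
is −ER restricted to genes passing the Library ES filter. AUC equals the
Mann–Whitney probability with ties counted 0.5. Against simulation truth,
`evaluate_truth` reports this AUC plus precision/recall of the final filter;
with zero truly essential genes it refuses the AUC and reports only the
filter's false-positive count. NTC pseudo-genes carry s = 1 and are scored
like any gene, so they can serve as a labeled non-essential class.

## Problem sizes used in the checks

The test suite runs simulations of 200–2,000 genes; the reference
parameter-recovery check uses the default conditions (2,000 genes × 6
guides, 3 replicates, 10% essential, 10-fold depletion, 90% efficiency,
500× depth, dispersion 0.1) over 5 seeds, and the null error-control check
uses twenty 500-gene screens with no essential genes. Counting round trips
are exercised up to ~1,000 guides × 13 samples. These sizes exercise every
code path while keeping a full run under a few minutes on one core.

## Known limitations

- The paired t-test with n = 3 replicates has df = 2: power is low and the
  final significant list is conservative; the ER ranking carries most of
  the discrimination (AUC ≈ 0.99 in the reference conditions while only a
  handful of genes clear p_adj < 0.05).
- Rank-based ES saturates at the extremes, so ER compresses toward 0 for
  genes whose guides were heavily lost in the Cas9-negative population;
  such genes are handled by the Library ES filter, not by the ER itself.
- Exact spacer matching tolerates no sequencing errors in the 20-mer; real
  FASTQ data with error rates above ~1%/base will undercount
  proportionally (uniformly across guides, so scores are largely
  unaffected, but depth is lost).
- Gain-of-function calls (positive ER) are deliberately out of scope; the
  method's own guidance is to interpret positive ER with caution.
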