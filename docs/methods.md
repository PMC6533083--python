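# Methods

## Outlier statistic

The statistic operates on a non-negative gene × sample matrix in RPKM-like
units. For each cell, `row_fold` divides by the gene's median across all
samples and `col_fold` divides by the median of all genes within the sample
(the focal gene included in that median). A cell is an outlier when **both**
folds strictly exceed their cutoffs; defaults are 32 (rowFold) and 64
(colFold). The statistic is computed on the full pan-lineage matrix, and
per-lineage structure is summarized afterwards — the medians are only
meaningful across the whole compendium.

Conventions, stated so that independent re-computations agree bit-for-bit:

- the median of an even-length vector is the mean of the two central order
  statistics;
- folds whose median denominator is zero are *undefined* (NaN), carried as
  data, and never outliers. An optional pseudocount (default 0), added to
  all values before the medians, is available for sensitivity analysis of
  that choice;
- strict `>` at both cutoffs: a rowFold of exactly 32 is not an outlier.

rowFold is invariant under rescaling any single gene's row by a positive
constant, colFold under rescaling any sample's column; the outlier set is
monotone non-increasing in each cutoff. These invariances are enforced by
property tests.

## Lineage enrichment and confinement

Outlier over-representation per (gene, lineage) uses the one-sided
hypergeometric tail P[X ≥ k] with N total samples, K outlier samples for
the gene, n samples in the lineage, and k outlier samples inside it. Only
pairs with k ≥ 1 are tested; Benjamini–Hochberg q-values are computed
across all tests performed. The hypergeometric choice is ours — it is the
standard exact over-representation test with correct small-sample behavior
— and the implementation is cross-checked in the test suite against direct
combinatorial enumeration for all N ≤ 30.

Confinement is a deliberately simple effect-size screen, complementary to
the enrichment p-value: score = mean(in-lineage) / (mean(out-of-lineage) +
0.01), with a gene called confined when score ≥ 10 and the in-lineage mean
is at least 1 RPKM. The pseudocount keeps exclusively-expressed genes
finite; the expression floor keeps silent genes out.

## Network inference from knockouts

A perturbation table holds relative expression (1 = unchanged) of each
measured gene after individually knocking out each member. Knockout k
drawing measured gene t (t ≠ k) down to ≤ 0.5 yields an activation edge
k→t; up to ≥ 2.0 a repression edge; edge magnitude is |log2(rel_expr)|.
The 2-fold symmetric thresholds are a configurable default — qPCR
fold-change calls in this range are conventional. Self-measurements (the
knockout's own residual expression) reflect editing efficiency, not
regulation, and are ignored. Replicate rows sharing a knockout id are
averaged on the log2 scale by the reader. The master regulator is the node
of maximal activation out-degree (activation only: the anchors this
analysis targets act as transcriptional activators); ties are all returned,
sorted.

Co-expression among regulon members uses Pearson (or Spearman) correlation
on log2(x + 1)-transformed values — the transform stabilizes RPKM skew; a
raw-scale option exists. Constant genes give flagged NaN results rather
than errors, and BH correction runs over the defined pairs.

## Bliss synergy

Dose matrices carry viability as a fraction of untreated control on two
ascending dose axes that each include 0. `normalize_viability` divides by
the untreated anchor and clamps into [0, 1], counting clamped cells.
Effects are fraction inhibition f = 1 − viability; the Bliss expectation
per cell is f_A + f_B − f_A·f_B with monotherapy effects read from the
observed 0-dose margins (no curve fitting — the analysis this supports fits
none). Excess = observed − expected inhibition; positive = synergy. The
scalar summary is the arithmetic mean of excess over strictly-combination
cells, with the maximum excess and its dose coordinates also reported; NaN
cells (unmeasured corners) are skipped. The margins have identically zero
excess, and the whole construction is symmetric under transposing the
matrix and swapping the drug labels.

## Screen analytics

The unit of analysis is the well: aggregate marker (e.g. nuclear
transcription-factor immunofluorescence) and nuclear-stain intensities as
instruments report them. Per-well ratio = marker / nuclear; wells labelled
`CONTROL` define the plate reference, and each ratio is divided by the
*median* control ratio (median for robustness to stray control wells;
normalization can be disabled). Compounds are ranked by ascending
normalized ratio — stronger suppression first — with lexicographic
tie-breaks on compound id, and the top k (default 15) are selected.
Ranking is invariant under any uniform positive rescaling of marker
intensities.

## Assay calculators

- **Relative expression (ΔΔCt)**: replicate Cts are averaged arithmetically
  on the Ct scale; ΔCt = mean Ct(target) − mean Ct(reference gene) within a
  condition; ΔΔCt subtracts the control condition's ΔCt; fold = 2^(−ΔΔCt).
  Amplification efficiency is fixed at 2.0 per cycle (no efficiency
  correction). The control condition's fold is exactly 1.
- **ChIP-qPCR percent input**: the input Ct is adjusted for the fraction of
  chromatin it was measured on (adjusted Ct = Ct_input − log2(1/fraction)),
  then percent input = 100 · 2^(adjusted Ct − Ct_IP). Fold enrichment
  divides by the percent input at a designated negative-control locus, and
  the promoter/intron region ratio divides mean enrichments over the two
  locus sets. The input dilution fraction is a required input — it cannot
  be inferred from Ct values.
- **Tumor volume**: V = L · W² · 0.52 in mm³ with L ≥ W enforced by
  swapping (caliper convention; the formula is asymmetric). Per-animal
  relative change is the ratio of last to first volume by measurement day;
  group summaries are mean ± sd.

## Synthetic data

The generators produce every input the pipeline consumes, with the
statistical structure the analyses assume. All of them are pure functions
of a spec plus a seed (per-generator streams are derived deterministically
from one global seed, so a single flag reproduces everything).

**Compendium.** 25 lineages × 25 samples and 2000 background genes by
default (~0.6 s to generate and analyze; the compendium it stands in for is
of the same order: ~700 samples, genome-wide genes). The background is
*hierarchical* log-normal: each gene draws a baseline log2 level from
N(3, 1.5²) across genes, and each sample scatters around its gene's
baseline with within-gene log2 sd 0.5. This mirrors real bulk RNA-seq —
enormous between-gene spread, modest within-gene spread — and is exactly
the structure the row-median scaling exists to remove; a flat per-cell
log-normal of the same marginal spread would instead produce heavy
per-cell tails that read as spurious outliers. Dropout zeros occur at rate
0.3 but only in cells whose underlying log2 expression is below a ceiling
(default log-mean + 2·log-sd): abundant transcripts are not measured as
zero RPKM, while background sparsity still produces genuine zero-median
genes that exercise the undefined-fold path. The planted regulon (PAX8
anchor + 8 members) has baselines pinned at the background log-mean — the
members emulate typically-expressed lineage genes — and is elevated by
2^7 in target-lineage samples, clearing the >32 rowFold cutoff with
margin. With these defaults the planted genes are recovered exactly and no
background gene recurs in the target lineage, robustly across seeds.

What the generator does *not* model: unequal lineage sizes (an optional
real compendium feature; sizes here are equal), batch effects, gene-length
or library-size artifacts, and correlated co-expression structure within
the background. Passing tests therefore demonstrate correctness of the
statistics and the recoverability of a planted signal under idealized
sampling — not robustness to those real-data nuisances.

**Perturbations.** A known directed network: the anchor activates every
member except the designated independent ones (default: all but FOLR1,
mirroring a regulon whose anchor drives all members but one); knockout of
the anchor lowers itself and its targets to `knockdown_effect` (default
0.3); knockout of any other member lowers only itself. Multiplicative
log2-normal replicate noise (sd 0.1) applies everywhere. Noiseless
simulations are recovered edge-for-edge by `infer_network` for any spec.

**Dose surfaces.** Hill-curve monotherapies (inhibition
d^h / (EC50^h + d^h)); combination inhibition is the Bliss expectation plus
a planted `bliss_excess_delta` in strictly-combination cells, clamped into
[0, 1], plus optional Gaussian noise. With zero delta and zero noise the
downstream excess is zero to 1e-12; a planted delta is recovered exactly in
unclamped cells. Default grids follow a 7 × 7 two-drug titration
(0–8 µM × 0–400 nM pattern).

**Screen.** 180 compounds, 15 planted suppressors at factor 0.2, 16
control wells, log2 ratio noise sd 0.05. Nuclear intensities vary
independently and cancel out of the ratio; with the default noise the
planted set separates cleanly from the baseline and top-15 selection
returns exactly the planted hits.

**qPCR.** Ct values follow 2-fold-per-cycle chemistry: a planted fold
change shifts the target's Ct by −log2(fold) relative to the control
condition, the reference gene is constant, and the control condition is
emitted with fold 1. The ΔΔCt calculator inverts this exactly at zero
noise.

## Numerical and serialization choices

- TSV is canonical; CSV is accepted on read by sniffing the header
  delimiter. Floats are written with `repr` and parsed with pandas'
  round-trip parser, so write/read is lossless (≥ 12 significant digits
  guaranteed, in practice exact).
- Identifiers are opaque case-sensitive strings; no symbol mapping.
- Missing cells are an error in expression matrices (medians are undefined
  under missingness) but tolerated in dose matrices off the untreated
  anchor, where Bliss scoring skips them.
- Validation is constructor-time: every container checks its invariants
  (non-negativity, unique ids, dimension agreement, dose monotonicity, Ct
  ranges, positive denominators) and names the offending row/column.

## Limitations

- The outlier cutoffs (32/64) are the published operating point of the
  statistic, not estimated from data; no FDR is attached to the outlier
  calls themselves (the enrichment stage carries the inference).
- Confinement's score threshold and expression floor are screening
  heuristics, not calibrated tests.
- Network inference treats each knockout independently and cannot
  distinguish direct from indirect regulation; membership of
  non-responsive genes in a regulon is a user decision.
- The Bliss summary is a plain mean over combination cells; it is not a
  response-surface model and carries no confidence interval.
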