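# Methods

## Overview

`promstate` analyses promoter-tiling ChIP-chip data for three histone
modifications (H3K4me3, AcH3, H3K27me3) measured against a general-H3
control across an ordered set of cell populations (by default monocyte →
macrophage and monocyte → dendritic cell), together with matched
replicate expression arrays. The package is organised as a pipeline of
pure functions over pandas containers; every stage can also be driven
from the `promstate` CLI or the `run_pipeline` driver.

## Normalization model

Raw channels are strictly positive linear intensities, one column per
(cell type, antibody). Three stages:

1. **Background scaling.** Each channel is divided by the ratio of its
   background-probe median to the grand median of all channels'
   background medians. The scaling is multiplicative — the natural
   choice for hybridisation intensities, which are ratio-scale — and
   leaves values positive. Zero or negative inputs are rejected rather
   than floored: a non-positive intensity indicates an upstream
   extraction problem that flooring would silently hide.
2. **H3 subtraction.** The per-probe track is
   log2(modification) − log2(H3), removing nucleosome-occupancy and
   probe-affinity effects shared by the two channels. The composition of
   stages 1–2 is exactly invariant under per-channel rescaling of the
   input (a tested identity).
3. **Differentiation delta.** Subtracting the progenitor's track
   probe-wise gives the gain (positive) or loss (negative) of a
   modification along differentiation.

## Peak calling

Each promoter tile is scanned with windows of `min_probes = 4`
consecutive probes scored by their mean track value. The null
distribution is built by permuting probe values within each chromosome
(`n_permutations = 200`, seeded) and re-scanning; pooled null window
scores estimate, for any threshold *t*, the false-discovery proportion
(#null windows > *t* / permutations) / (#observed windows > *t*). The
smallest *t* with estimated FDR ≤ 0.05 is chosen; windows strictly above
*t* are significant (ties at the threshold are conservatively dropped)
and significant windows sharing ≥1 probe merge into a peak whose score
is the mean over the merged probes. Window means never cross tile
boundaries. Within-chromosome (rather than global) permutation preserves
any chromosome-scale intensity offsets under the null.

Marginally, a permuted window is a uniformly random `min_probes`-subset
of the chromosome's probe values; the test suite checks the pooled null
against exhaustive enumeration of all C(n, k) subsets on a small tile.

The per-gene **delta score** summarising a differentiation-delta track is
the sliding-window mean of largest magnitude inside the promoter, signed
(gain vs loss). Genes with fewer than `min_probes` probes are reported
as uncallable (NaN), distinct from a zero score.

## Promoter windows and assignment

Promoter windows span 2000 bp upstream to 500 bp downstream of the TSS
in transcription direction; minus-strand genes use the mirrored interval
`[tss − 499, tss + 2001)` so every window is 2500 bp, half-open, 0-based,
and contains the TSS. A gene is marked when ≥1 called peak overlaps its
window by ≥1 bp (no minimum overlap fraction); the gene's score is the
best overlapping peak score. Metaprofiles bin probe midpoints by signed
TSS distance (strand-aware, 50 bp bins) and average track values per bin.

## Chromatin states and statistics

The three boolean marks define 8 combinatorial states. Frequencies are
percentages over a gene subset. Cross-mark correlation is Pearson on the
gene × (cell type, mark) matrix of boolean calls by default (continuous
peak scores via a flag); zero-variance columns produce NaN entries
rather than silent zeros. Mark-vs-expression enrichment compares the
mark's frequency among the top-*n* and bottom-*n* genes by expression
(ties broken by stable gene-id order) with a two-sided Fisher exact test
on the 2×2 top/bottom × marked/unmarked table. "Expressed" vs "inactive"
gene sets default to a 75th-percentile cut on mean signal — a stand-in
for platform detection calls, configurable.

State dynamics are 8×8 contingency tables between two populations over
their shared gene universe; genes uncallable in either endpoint are
excluded from the table (and countable by the caller). The persistence
summary reports per starting state the fraction retained, the fraction
moving to each other state, and the headline instability statistic for
the lone H3K4me3 mark (fraction lost or converted, mostly to the
H3K4me3/AcH3 double mark).

## Expression analysis

Rank-invariant normalization: per sample, genes whose expression rank
differs from the reference sample's rank by < 5% of the gene count form
the invariant set; the sample is divided by the median sample/reference
ratio over that set (iterated to convergence; scaling preserves ranks,
so convergence is immediate). Differential calls use the ratio of linear
replicate means (fold change) and a two-sided two-sample t test on log2
replicates; a gene is up (down) when fold ≥ 2 (≤ 0.5) and p < 0.05, with
no multiple-testing correction by default, matching the analysis style
the pipeline emulates (Benjamini–Hochberg available via a flag).

**Variance model.** The default t test pools variances. With only three
replicates per group, the unequal-variance (Welch) variant is measurably
conservative — its Satterthwaite degrees of freedom fall below the
pooled value, deflating the null rejection rate to ≈0.039 instead of
0.05 — whereas the pooled test is exact under the generator's lognormal
replicate model. `welch=True` restores the unequal-variance behaviour
for data with genuinely heteroskedastic groups.

## Synthetic world

The generator states a world and keeps it fixed:

- **Layout.** Genes in 10 kb slots across chromosomes (windows can never
  overlap), TSS jittered within the slot, strands ~50/50. Each 2.5 kb
  window is tiled by 25 probes (50-mer, 100 bp spacing); 2000 background
  probes sit ≥500 bp clear of any window.
- **States.** First cell type drawn from a prior chosen so single-mark
  marginals approximate genome-wide monocyte promoter frequencies
  (H3K4me3 ≈ 45%, AcH3 ≈ 30%, H3K27me3 ≈ 23%, no mark ≈ 36%, double
  active mark ≈ 26%). Each differentiated population is drawn
  independently from the progenitor through an 8×8 kernel in which the
  double mark persists (80%), lone active marks are unstable (75–85%
  leave, mostly to "none" or the double mark), and H3K27me3 alone is
  stable (85%) — the qualitative dynamics of monocyte differentiation.
- **Signal.** H3 is lognormal with geometric mean 1000 (arbitrary but
  stated) and log2-sd 0.5. Marked active channels multiply H3 by
  2^2.0 in two lobes (−800..−200 and +100..+400 bp around the TSS) and
  by 2^(2.0·0.4) between them — a 60% dip at the start site, where
  nucleosomes are depleted in vivo. H3K27me3 enrichment is uniform
  across the window. All channels add Gaussian log2 noise (sd 0.3).
- **Expression.** Replicates (3 per cell type; the emulated study never
  states its replicate count) are lognormal around per-state log2 means
  ordered K4+Ac (10) > K4 = Ac (8) > bivalent (6) > none (5) > K27
  (3.5), replicate sd 0.5.

What the generator does **not** emulate: probe-sequence affinity
differences, cross-hybridisation, dye/scanner saturation, spatial array
artefacts, multi-isoform promoters, or correlated replicate structure.
A green recovery test therefore establishes that the algorithms are
correct and calibrated on well-behaved signal of realistic shape and
magnitude — not that they are robust to every platform pathology.

## Numerical choices

- Intervals are 0-based half-open everywhere, including BED output;
  abutting intervals do not overlap.
- Peak-threshold ties are non-significant; the FDR threshold is the
  smallest achieving the target, maximising discoveries at the stated
  control level.
- The permutation machinery, state draws and noise all derive from a
  single integer seed through seeded generators; every pipeline output
  is bit-reproducible (the manifest checksums are the test).
- Fisher p-values use the exact hypergeometric two-sided definition
  (sum of tables with probability ≤ observed).
- Genes without probes are "uncallable" and excluded from transition
  tables, never imputed.

## Known limitations

- The peak caller is a transparent stand-in for the closed-source
  scanner software used on the original platform; absolute peak scores
  are not comparable to that tool's internal scores.
- The rank-invariant implementation follows the published description of
  the method class, not any vendor's proprietary variant.
- One promoter per gene is assumed; arrays with several promoters per
  gene need pre-collapsing.
- Enrichment P-values on real data depend on detection calls and
  replicate structure the emulated design leaves unstated; only the
  direction and order of magnitude are meaningful for comparison.
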