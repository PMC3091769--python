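# promstate

Promoter histone-modification state analysis for tiled ChIP-chip arrays
with matched expression data.

## The problem

During the differentiation of human monocytes (MO) into macrophages (MF)
or dendritic cells (DC), promoters gain and lose histone modifications
that track — and partly anticipate — changes in transcription. A classic
assay for this is promoter tiling-array ChIP-chip: chromatin is
immunoprecipitated with antibodies against H3K4me3, AcH3 and H3K27me3
(plus general H3 as a control) and hybridised to ~2.5 kb promoter tiles of
50-mer probes, while matched bead arrays measure mRNA levels.

`promstate` implements the complete downstream analysis of such a design:

1. **Normalization** — per-channel scaling to random genomic background
   probes, then the per-probe log2(modification/H3) ratio, then optional
   subtraction of the progenitor track (differentiation delta).
2. **Peak calling** — sliding windows of ≥4 consecutive probes scored by
   mean log2 ratio against a within-chromosome permutation null, with
   FDR-controlled thresholding and merging of overlapping windows.
3. **Promoter assignment** — peaks mapped to genes where they fall in the
   −2000/+500 bp window around the TSS (strand-aware, 0-based half-open),
   plus TSS-anchored metaprofiles.
4. **Chromatin states** — the three boolean marks combine into 8
   promoter states (none, single marks, the active H3K4me3/AcH3 double
   mark, the bivalent H3K4me3/H3K27me3 mark, …); frequencies, cross-mark
   Pearson correlations and Fisher-exact mark enrichment among the most /
   least expressed genes.
5. **State dynamics** — 8×8 transition tables MO→MF and MO→DC with
   per-state persistence summaries.
6. **Expression analysis** — rank-invariant normalization, differential
   calls at the 2-fold & P<0.05 criterion, and exclusive/shared overlap
   accounting between the two differentiated lineages.

Because the original array data live in public repositories and depend on
proprietary scanner internals, the package ships a first-class
**synthetic-data generator**: it plants per-gene 3-bit mark states from a
prior, evolves them through a differentiation transition kernel, renders
probe intensities with the characteristic bimodal active-mark shape (two
enrichment lobes flanking a dip at the TSS) versus flat repressive
H3K27me3 signal, and couples replicate expression values to the planted
state. Every downstream stage is tested against this planted truth.

## Worked example

```python
import promstate as ps

params = ps.SimParams(n_genes=1000, n_chroms=5, seed=5)
ann, probes, truth, intens, expr = ps.simulate_all(params)
windows = ps.promoter_windows(ann)

calls, tracks, peaks = ps.chip_mark_calls(
    intens, probes, windows, params.cell_types, seed=5
)
states = ps.classify_states(calls)
print(ps.state_frequencies(states.query("cell_type == 'MO'")).round(1))
```

prints the recovered monocyte state frequencies (percent of promoters):

```
none         35.2
K4           14.9
Ac            1.5
K27          16.6
K4+Ac        24.3
K4+K27        5.6
Ac+K27        1.3
K4+Ac+K27     0.6
```

— the double H3K4me3/AcH3 mark is the most common modified state and
roughly a third of promoters carry no mark, matching the planted prior.
Continuing,

```python
tab = ps.transitions(states.query("cell_type=='MO'"),
                     states.query("cell_type=='MF'"))
print(ps.k4_alone_fate(tab))              # 0.792
top, bottom, p = ps.expression_enrichment(
    calls, expr["MO"].mean(axis=1), "H3K4me3", n=200, cell_type="MO"
)
print(top.frequency, bottom.frequency, p)  # 100.0 0.0 1.9e-119
```

shows that ~79% of promoters carrying H3K4me3 alone in monocytes lose it
or convert to the double mark in macrophages (the planted kernel sends
75% away; the remainder is sampling noise), and that H3K4me3 is overwhelmingly enriched on the most highly
expressed genes.

## Command line

`promstate` exposes each stage (`simulate`, `normalize`, `callpeaks`,
`assign`, `metaprofile`, `states`, `dynamics`, `express`) plus `run`,
which executes the whole pipeline from a YAML config and writes a
checksummed manifest:

```bash
promstate run --outdir out/ --seed 1
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full 2000-gene synthetic pipeline from scratch — simulation,
normalization, peak calling for all nine (cell type × modification)
channels, state classification, dynamics and differential expression —
and writes the results-summary JSON. It completes in well under a minute
on one CPU.
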