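# chromprime

Summit-anchored differential chromatin accessibility, transcription-factor
motif enrichment scoring, ChIP-seq/expression integration, and a
randomisation-based **lineage-priming** enrichment test — packaged as a
tested Python library with a `chromprime` command line and a synthetic-data
generator, so the whole analysis runs and validates at desk scale.

## The problem

During blood cell development, the chromatin of progenitor cells is
*primed*: accessible regulatory regions of mature lineages
(megakaryocyte, erythroblast, monocyte, B cell, CMP) are already open
before the corresponding expression programs switch on. Perturbing a
master regulator — e.g. inducing a mutant transcription factor with
doxycycline in an otherwise healthy progenitor — changes which regions of
the genome are accessible, and therefore which lineages remain primed.
`chromprime` implements the computations needed to quantify this from
ATAC-seq/ChIP-seq peak calls and signal tracks:

1. **Differential accessibility.** Peaks from the paired −dox/+dox
   conditions are merged into a union (summits within 400 bp merge
   transitively; the union summit is the mean of member summits). The
   average tag density in a 400-bp window centred on each union summit is
   read from each condition's bedGraph, normalised to counts-per-million
   (CPM, promoter-proximal and distal peaks separately), and a peak is
   called *gained* / *lost* when

   `fold = (CPM₊ + 1) / (CPM₋ + 1)` is ≥ 2 (resp. ≤ ½), *shared* otherwise.

2. **Motif enrichment.** For motif *i* in peak set *j* with hit count
   `n_ij` out of `m_j` peaks,

   `S_ij = (n_ij / m_j) / (Σ_j n_ij / Σ_j m_j)`,

   the set-level motif frequency relative to the pooled frequency
   (S = 1 ⇒ background rate; the scores satisfy
   Σ_j m_j S_ij / Σ_j m_j = 1 for every motif).

3. **Lineage priming.** Cell-type-specific chromatin signatures are the
   peaks reproducible in every replicate of one mature cell type and
   absent from all others. For a set of n condition-specific peaks, the
   observed signature overlap x is compared with 1,000 size-matched
   uniform draws (without replacement) from the full distal peak universe:

   `z = (x − μ) / σ`,

   with μ, σ the resample mean and SD, and the empirical enrichment
   p-value the proportion of resample counts strictly greater than x.
   Because draws are uniform without replacement, the null is exactly
   hypergeometric — the closed form used as the independent oracle in the
   test suite.

4. **Integration.** ChIP peaks are filtered to open chromatin, tested with
   the same fold rule (800-bp windows for broad marks such as H3K27ac),
   summarised as average profiles and UpSet-style exclusive combination
   counts; differential-expression tables are classified into seven
   cross-condition trajectory categories and compared pairwise.

## Worked example

Everything below runs from scratch in a few seconds — the generator plants
ground truth (a fourfold accessibility change in 10% of peaks each way,
and 40% of the gained peaks drawn from the `celltype_A` signature against
a 10% background), and the pipeline recovers it:

```python
from chromprime import (AtlasSpec, ExperimentSpec, simulate_atlas,
                        simulate_experiment, derive_signatures,
                        build_peak_union, differential_table, priming_panel)

atlas = simulate_atlas(AtlasSpec(peaks_per_type=500, genome_length=10_000_000), seed=17)
signatures = derive_signatures(atlas.replicates)
exp = simulate_experiment(
    ExperimentSpec(n_union_peaks=2000, signature_enrichment={"celltype_A": 0.4}),
    atlas, seed=18)

union = build_peak_union(exp.peaks_minus, exp.peaks_plus)
table = differential_table(union, exp.track_minus, exp.track_plus)
print(table["class"].value_counts().to_dict())

panel = priming_panel(table, signatures, n_resamples=1000, seed=17, classes=("gained",))
print(panel[["class", "cell_type", "x", "mu", "sigma", "z", "p_enrich"]]
      .round(3).to_string(index=False))
```

prints

```
{'shared': 1585, 'gained': 211, 'lost': 204}
 class  cell_type  x     mu  sigma      z  p_enrich
gained celltype_A 66 19.104  3.968 11.819     0.000
gained celltype_B 20 19.877  3.989  0.031     0.451
gained celltype_C 19 19.371  3.988 -0.093     0.476
gained celltype_D 18 18.337  3.774 -0.089     0.481
gained celltype_E 20 18.919  4.134  0.261     0.338
```

The 211 gained and 204 lost peaks recover the planted ~10% classes; the
planted cell type stands out (66 of 211 gained peaks hit its signature
against a resampling mean of 19.1, z = 11.8, empirical p < 0.001) while
the four unplanted lineages sit at their background rate (|z| < 0.3).

The same analysis is available from the shell, e.g.

```bash
chromprime diffacc --minus m.narrowPeak --plus p.narrowPeak \
    --track-minus m.bedGraph --track-plus p.bedGraph --out diff.tsv
chromprime priming --test gained.bed --universe distal_union.bed \
    --signature megakaryocyte.bed --n-resamples 1000 --seed 17 --out priming.tsv
chromprime run --config pipeline.yaml   # all stages, manifest.json with content hashes
```

## Layout

| module | contents |
| --- | --- |
| `chromprime.intervals` | interval/peak model, BED/narrowPeak I/O, overlap + nearest-gene sweeps |
| `chromprime.tracks` | bedGraph step-function tracks, exact windowed/binned means |
| `chromprime.diffacc` | peak union, CPM + log2 normalisation, fold calls, ranked density matrices, correlation clustering |
| `chromprime.chip` | open-chromatin filtering, mark-specific differential windows, average profiles, UpSet counts, TF-target fractions |
| `chromprime.motifs` | S_ij score matrix, clustering, motif density matrices |
| `chromprime.expression` | expression filter, trajectory categories, pairwise DE overlaps, fold-change correlation |
| `chromprime.priming` | signature derivation, resampling test, per-condition panels |
| `chromprime.simulate` | seed-deterministic synthetic fixtures with planted ground truth |
| `chromprime.pipeline` / `chromprime.cli` | YAML-configured orchestration, manifest with content hashes, `chromprime` CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
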