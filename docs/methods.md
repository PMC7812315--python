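# Methods

This note documents the statistical procedures implemented in
`chromprime`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions used in
edge cases.

## Coordinate and overlap conventions

All coordinates are 0-based, half-open (BED convention). narrowPeak summit
offsets are 0-based from the interval start; an offset of −1, or a format
without a summit column, falls back to the interval midpoint rounded down.
*Overlap* always means at least one shared base, the `bedtools intersect`
default; touching half-open intervals do not overlap. Nearest-gene
assignment measures summit-to-TSS distance, breaks exact-distance ties to
the lexicographically smallest gene id (for deterministic output), carries
strand but does not use it, and assigns peaks on gene-free chromosomes to
the sentinel `unassigned`.

## Differential accessibility

**Peak union.** Peaks of the two conditions whose summits lie within
`summit_distance` (default 400 bp) merge *transitively*: after sorting by
summit, a new group starts when the gap to the previous summit exceeds the
threshold, which in one dimension is exactly the transitive closure of the
pairwise relation (verified against an all-pairs oracle in the tests). The
merged summit is the floor of the mean of all member summits — for two
members, the midpoint between the original summits; the two-peak midpoint
rule generalised to chains this way keeps the summit inside the merged
span. The merged interval runs from the minimum start to the maximum end.

**Windowed density.** The tag density of a peak is the mean of the
bedGraph step function over the half-open window
`[summit − w/2, summit + w/2)` (default w = 400 bp), computed exactly from
the cumulative integral of the track, so results do not depend on how the
track is segmented. Windows truncated at position 0 keep the divisor at
`w` — off-chromosome bases count as zero coverage — the simplest
contract that is consistent for every window and avoids inflating
densities at chromosome starts.

**Normalisation.** Each condition's densities are scaled to
counts-per-million (column sums exactly 10⁶) and log-transformed as
log2(CPM + 1). Promoter-proximal peaks (summit within 1.5 kb of a TSS,
boundary inclusive) and distal peaks are normalised and analysed
separately; each element class forms its own million. Absolute CPM values
therefore depend on the upstream scaling of the input tracks; the module
accepts any non-negative track and only the *ratios* between conditions
matter downstream.

**Calls.** `fold = (CPM₊ + 1)/(CPM₋ + 1)`; gained iff fold ≥ t, lost iff
fold ≤ 1/t (default t = 2, boundary counts as differential), shared
otherwise. The pseudocount of 1 CPM makes zero-coverage peaks well defined
and is negligible against typical per-peak CPM values (~10²–10³). The rule
is exactly antisymmetric: swapping the condition columns swaps gained and
lost labels and maps fold to 1/fold.

**ChIP marks.** Differential ChIP analysis reuses the same code path with
a mark-specific window — 400 bp for point-source factors, 800 bp for broad
marks such as H3K27ac, centred on the ATAC union summit (not the ChIP
peak) so that signal on the flanking nucleosomes of an open site is
counted. "Within open chromatin" means any-base overlap with an ATAC
peak, not summit containment. ChIP replicate handling is single-track by
design (immunoprecipitations are typically pooled before library
preparation); the module models no replicate variance.

## Motif enrichment score

`S_ij = (n_ij/m_j) / (Σ_j n_ij / Σ_j m_j)` — the motif frequency in peak
set *j* relative to the pooled frequency across sets. Two identities
follow algebraically and are asserted on random inputs: the m-weighted
mean of each motif's scores is 1 (to 10⁻⁹), and S is invariant to scaling
all n and m by a constant. Motifs observed in no set would give 0/0 and
are dropped with a warning. Where the hits come from is out of scope: any
scanner's binary per-peak hit table aggregates to the required counts.
Heat-map displays sometimes normalise further; the writer optionally
emits a per-row z-scored copy, clearly labelled as a display transform —
the exported score matrix itself is always raw S.

Hierarchical clusterings (motif scores, sample correlations, fold-change
correlations) all use complete linkage on Euclidean distances; leaf orders
come from the deterministic agglomeration sequence, with ties resolved by
input order, so equal inputs give equal orderings.

## Lineage priming

**Signatures.** Per mature cell type, *reproducible* peaks are the peaks
of replicate 1 that overlap every other replicate; the *signature* keeps
the reproducible peaks with zero overlap against the union of all other
cell types' reproducible peaks. A region claimed by two cell types is
excluded from both.

**Test.** For a test set of n condition-specific distal peaks against a
signature: x is the number of test peaks overlapping the signature
(a peak overlapping several signature peaks counts once); each of
`n_resamples` (default 1,000) draws takes n distinct peaks uniformly
without replacement from the full distal universe — gained, lost and
shared peaks alike — and records its overlap count. Then
`z = (x − μ)/σ` with μ and the *population* SD σ over the resampled
counts, `p_enrich = #{count > x}/n_resamples` (low value ⇒ enrichment)
and `p_deplete = #{count < x}/n_resamples`, both with strict
inequalities; an optional `smoothed` flag switches to
`(#{count ≥ x} + 1)/(n + 1)` for users needing p > 0. When σ = 0 (the
signature covers all of the universe or none of it) the result is
flagged degenerate and z is reported as undefined rather than ±∞.

Sampling without replacement makes the null count exactly
hypergeometric(N, K, n) with N the universe size and K the number of
signature-overlapping universe peaks; the tests use this closed form as an
independent oracle for μ, σ, the tail probability, and monotonicity of z
and p in x. Strict-inequality empirical p-values are conservative
(super-uniform) under the null; because the resample counts are discrete,
calibration is checked with the one-sided Kolmogorov–Smirnov statistic D⁺
(the ECDF must not rise above the uniform CDF) — a two-sided test would
reject for discreteness alone.

Each test in a panel derives its own sub-seed by hashing the master seed
with the condition, class and cell-type labels, so adding a cell type
never perturbs another test's draws. The null is deliberately plain
uniform resampling from the distal universe — no GC, length or
distance-matched backgrounds.

## Expression integration

Genes are considered expressed with ≥ 50 reads in at least one sample.
A gene is de-regulated at linear |fold| ≥ 2, combined with adjusted
p < 0.05 when the table carries an adjusted-p column (fold alone
otherwise). The seven trajectory categories (up/down in both conditions,
up/down in one only, unchanged) are a partition: each gene maps to
exactly one. Genes discordant between conditions (up in one, down in the
other) are assigned to the condition with the larger |log2 fold|, ties to
the up-regulated condition — the unique simple rule that keeps the map
exhaustive, exclusive, and exactly symmetric under swapping conditions.
Figure-style tallies that count a discordant gene in both "-only" bins
are provided separately (`trajectory_tallies`, default on), and both
conventions are reported where they differ. Fold-change correlations use
the union of de-regulated genes as the feature space, imputing log2fc = 0
for genes missing from a contrast (dropping them instead is exposed as a
flag).

## Synthetic data

The generator produces, from one seed, byte-identical fixtures with
planted truth:

* **Atlas** — default 5 cell types × 2,000 peaks of 400 bp on a single
  60-Mb synthetic chromosome `chrS`; 60% of each type's peaks are
  exclusive to it and the rest shared by all types; two replicates per
  type with 5% independent peak dropout. The 60% exclusive fraction is
  sized so each signature comfortably supplies the 10%-of-universe
  background pool the experiment draws on.
* **Experiment** — default 10,000 union peaks: for each cell type, 10% of
  the universe is placed directly on that type's exclusive peaks
  (signatures are disjoint, so each universe peak carries at most one
  label); the rest lands in atlas-free genome space. 10% of peaks are
  planted gained and 10% lost at fourfold; each class's composition keeps
  every cell type at its background rate unless an enrichment fraction is
  given (so planting one signature does not mechanically deplete the
  others), with the default scenario planting 40% of gained peaks from
  one signature. Densities get multiplicative log-normal noise with
  CV = 0.2 per condition; +dox summits are jittered ±50 bp. Peaks are
  placed with ≥ 500 bp gaps so distinct planted peaks can never
  summit-merge — real post-merge peak calls are similarly separated.
* **Motifs** — per-set Bernoulli hits with one uniform position per
  carrying peak. **Expression** — noiseless fold pairs per planted
  trajectory category.

These fixtures exercise every code path but are idealised: no read-level
noise, uniform peak widths, a single chromosome (a dedicated test covers
multi-chromosome inputs), independent peaks, and noise that is exactly
log-normal. Passing the recovery tests therefore demonstrates the
*correctness of the computations under their own assumptions*, not
robustness to the full complexity of real ATAC-seq data.

## Problem sizes and defaults

| parameter | default | note |
| --- | --- | --- |
| summit merge distance | 400 bp | union construction |
| density window | 400 bp (800 broad marks) | centred on union summit |
| promoter window | 1,500 bp | boundary inclusive |
| fold threshold | 2 | boundary counts as differential |
| heatmap window / bin | 2,000 / 10 bp | 200 bins per peak |
| average-profile window | 4,000 bp | ±2 kb around references |
| resamples | 1,000 | 100,000 in the oracle check |
| atlas | 5 types × 2,000 peaks | 2 replicates, 5% dropout |
| universe | 10,000 distal peaks | 10% background signature rate |

The validation scripts use these sizes (with 10 generator seeds for the
recovery rates and 200 simulated tests for null calibration); all stages
complete in seconds to a couple of minutes on one CPU.

## Known limitations

* No replicate-aware statistical model for accessibility or ChIP signal —
  calls are plain fold ratios, as intended.
* Empirical p-values have resolution 1/n_resamples and are exactly 0 when
  no resample beats the observation; use the smoothed variant when a
  nonzero p is required.
* The priming null corrects for set size only; covariate-matched
  backgrounds are out of scope.
* Absolute CPM values depend on upstream track scaling; only
  between-condition ratios are interpretable.
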