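"""Seed-deterministic synthetic fixtures with planted ground truth.

Every generator emulates the statistical structure one stage of the
pipeline assumes — a replicated mature-cell-type peak atlas with exclusive
(cell-type-specific) peaks, a paired −dox/+dox accessibility experiment
with planted fold changes and a planted signature enrichment among the
gained peaks, Bernoulli motif hits, and trajectory-classified expression
tables — and returns the planted labels alongside, so each stage has an
exact recovery target.  All coordinates live on a single synthetic
chromosome ``chrS``; peaks never overlap each other within a fixture.

What these fixtures do *not* emulate: read-level noise, fragment-length
structure, GC bias, multi-chromosome genomes (one dedicated test adds a
second chromosome), or correlated peak widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, PeakSet, unique_names
from .motifs import MotifCounts
from .tracks import TagTrack

__all__ = [
    "AtlasSpec",
    "ExperimentSpec",
    "AtlasResult",
    "ExperimentResult",
    "simulate_atlas",
    "simulate_experiment",
    "simulate_motifs",
    "simulate_de_tables",
]

CHROM = "chrS"


@dataclass(frozen=True)
class AtlasSpec:
    """Replicated mature-cell atlas layout.

    ``specific_fraction`` of each cell type's peaks are exclusive to it;
    the rest are shared across all types.  ``replicate_jitter`` is the
    probability that any one peak drops out of any one replicate.
    """

    n_celltypes: int = 5
    peaks_per_type: int = 2000
    specific_fraction: float = 0.6
    genome_length: int = 60_000_000
    peak_width: int = 400
    min_gap: int = 500
    replicate_jitter: float = 0.05
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.specific_fraction <= 1:
            raise ValueError("specific_fraction must lie in [0, 1]")
        if not 0 <= self.replicate_jitter < 1:
            raise ValueError("replicate_jitter must lie in [0, 1)")
        if self.n_celltypes < 2:
            raise ValueError("need >= 2 cell types")


@dataclass(frozen=True)
class ExperimentSpec:
    """Paired −dox/+dox experiment with planted classes and priming.

    ``signature_enrichment`` maps a cell type to the fraction of *gained*
    peaks drawn from universe peaks overlapping that type's signature
    (``lost_signature_enrichment`` does the same for lost peaks);
    ``background_signature_rate`` is the fraction of the whole universe
    placed on each cell type's signature.  ``noise_cv`` is the coefficient
    of variation of the multiplicative log-normal noise on window
    densities.
    """

    n_union_peaks: int = 10_000
    gained_fraction: float = 0.1
    lost_fraction: float = 0.1
    planted_fold: float = 4.0
    noise_cv: float = 0.2
    background_signature_rate: float = 0.1
    signature_enrichment: Mapping[str, float] = field(default_factory=dict)
    lost_signature_enrichment: Mapping[str, float] = field(default_factory=dict)
    peak_width: int = 400
    min_gap: int = 500
    summit_jitter: int = 50
    density_range: tuple[float, float] = (5.0, 50.0)

    def __post_init__(self) -> None:
        if self.gained_fraction + self.lost_fraction > 1:
            raise ValueError("gained_fraction + lost_fraction must be <= 1")
        for m in (self.signature_enrichment, self.lost_signature_enrichment):
            if sum(m.values()) > 1:
                raise ValueError("signature enrichment fractions sum > 1")
            if any(not 0 <= v <= 1 for v in m.values()):
                raise ValueError("enrichment fractions must lie in [0, 1]")
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class AtlasResult:
    replicates: dict[str, list[PeakSet]]
    truth: pd.DataFrame  # columns: name, chrom, start, end, summit, label
    spec: AtlasSpec


@dataclass
class ExperimentResult:
    peaks_minus: PeakSet
    peaks_plus: PeakSet
    track_minus: TagTrack
    track_plus: TagTrack
    truth: pd.DataFrame  # per universe peak: name, class, signature, base_density
    spec: ExperimentSpec


def _nonoverlapping_starts(
    n: int, genome_length: int, width: int, rng: np.random.Generator,
    min_gap: int = 0,
) -> np.ndarray:
    """n sorted start positions for ``width``-bp peaks, >= ``min_gap`` bp apart.

    The gap keeps summits of distinct peaks farther apart than the default
    union merge distance, so a planted peak never chain-merges with its
    neighbour.
    """
    eff = width + min_gap
    slack = genome_length - n * eff
    if slack < 0:
        raise ValueError(
            f"{n} peaks of {width} bp (+{min_gap} bp gap) do not fit in "
            f"{genome_length} bp"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    return offsets + eff * np.arange(n)


def simulate_atlas(spec: AtlasSpec, seed: int) -> AtlasResult:
    """Replicated per-cell-type peak sets with planted specificity labels."""
    rng = np.random.default_rng(seed)
    types = [f"celltype_{chr(ord('A') + i)}" for i in range(spec.n_celltypes)]
    n_specific = int(round(spec.peaks_per_type * spec.specific_fraction))
    n_shared = spec.peaks_per_type - n_specific
    total = n_shared + spec.n_celltypes * n_specific
    starts = _nonoverlapping_starts(
        total, spec.genome_length, spec.peak_width, rng, spec.min_gap
    )
    names = unique_names("atlas_", total)
    labels = ["shared"] * n_shared + [
        t for t in types for _ in range(n_specific)
    ]
    order = rng.permutation(total)  # decouple genomic order from label blocks
    labels = [labels[i] for i in order]
    truth = pd.DataFrame(
        {
            "name": names,
            "chrom": CHROM,
            "start": starts,
            "end": starts + spec.peak_width,
            "summit": starts + spec.peak_width // 2,
            "label": labels,
        }
    )
    peaks_by_name = {
        r.name: Peak(
            GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.summit), r.name
        )
        for r in truth.itertuples()
    }
    replicates: dict[str, list[PeakSet]] = {}
    for t in types:
        member_names = truth.loc[
            truth["label"].isin(["shared", t]), "name"
        ].tolist()
        reps = []
        for r in range(spec.n_replicates):
            keep = rng.random(len(member_names)) >= spec.replicate_jitter
            reps.append(
                PeakSet(
                    [peaks_by_name[nm] for nm, k in zip(member_names, keep) if k],
                    label=f"{t}_rep{r + 1}",
                )
            )
        replicates[t] = reps
    return AtlasResult(replicates=replicates, truth=truth, spec=spec)


def _pick(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    if k > len(pool):
        raise ValueError("not enough peaks in pool for requested draw")
    return rng.choice(pool, size=k, replace=False)


def simulate_experiment(
    spec: ExperimentSpec, atlas: AtlasResult, seed: int
) -> ExperimentResult:
    """Paired condition peak sets + tracks with planted differential classes.

    Universe peaks are placed either directly on a cell-type signature peak
    (``background_signature_rate`` of the universe per type — signatures are
    disjoint, so each peak belongs to at most one) or in atlas-free genome
    space.  Gained/lost membership is then drawn from the signature-linked
    pools per the enrichment maps, remainder uniform.  Densities: every
    peak gets a base density; gained peaks are multiplied by
    ``planted_fold`` in +dox, lost peaks in −dox, and every window density
    receives independent log-normal noise with CV ``noise_cv``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_union_peaks
    types = sorted({l for l in atlas.truth["label"] if l != "shared"})
    n_bg = int(round(spec.background_signature_rate * n))

    # signature-linked universe peaks reuse the planted specific coordinates
    sig_rows = []
    for t in types:
        pool = atlas.truth.index[atlas.truth["label"] == t].to_numpy()
        take = _pick(rng, pool, n_bg)
        for i in take:
            sig_rows.append((t, i))
    n_free = n - len(sig_rows)
    if n_free < 0:
        raise ValueError("background_signature_rate × cell types exceeds 1")

    # free peaks: candidates spaced by min_gap, rejected if within min_gap
    # of any atlas peak (so they can never summit-merge with one)
    atlas_starts = atlas.truth["start"].to_numpy() - spec.min_gap
    atlas_ends = atlas.truth["end"].to_numpy() + spec.min_gap
    candidates = _nonoverlapping_starts(
        min(3 * n_free + 64,
            atlas.spec.genome_length // (spec.peak_width + spec.min_gap)),
        atlas.spec.genome_length,
        spec.peak_width,
        rng,
        spec.min_gap,
    )
    cand_end = candidates + spec.peak_width
    hits = np.searchsorted(atlas_starts, cand_end, side="left") - np.searchsorted(
        np.sort(atlas_ends), candidates, side="right"
    )
    free = candidates[hits == 0][:n_free]
    if len(free) < n_free:
        raise ValueError("genome too crowded to place signature-free peaks")

    rows = []
    for t, i in sig_rows:
        r = atlas.truth.loc[i]
        rows.append((int(r["start"]), int(r["end"]), int(r["summit"]), t))
    for s in free:
        s = int(s)
        rows.append((s, s + spec.peak_width, s + spec.peak_width // 2, "none"))
    rows.sort()
    truth = pd.DataFrame(rows, columns=["start", "end", "summit", "signature"])
    truth.insert(0, "chrom", CHROM)
    truth.insert(0, "name", unique_names("exp_", len(truth)))

    # planted classes
    n_gained = int(round(spec.gained_fraction * n))
    n_lost = int(round(spec.lost_fraction * n))
    cls = np.array(["shared"] * n, dtype=object)
    available = np.ones(n, dtype=bool)

    def assign(count: int, enrichment: Mapping[str, float], label: str) -> None:
        # cell types without an explicit planted fraction stay at the
        # background rate, so planting one signature cannot mechanically
        # deplete the others in a size-matched class
        full = {
            t: enrichment.get(t, spec.background_signature_rate) for t in types
        }
        if sum(full.values()) > 1:
            raise ValueError("class composition fractions sum > 1")
        chosen: list[int] = []
        for t, frac in sorted(full.items()):
            k = int(round(frac * count))
            pool = np.flatnonzero(available & (truth["signature"] == t).to_numpy())
            take = _pick(rng, pool, k)
            chosen.extend(int(i) for i in take)
            available[take] = False
        rest = count - len(chosen)
        # remainder comes from signature-free peaks so every cell type ends
        # at exactly its target fraction of the class
        pool = np.flatnonzero(available & (truth["signature"] == "none").to_numpy())
        take = _pick(rng, pool, rest)
        chosen.extend(int(i) for i in take)
        available[take] = False
        cls[np.asarray(chosen, dtype=int)] = label

    assign(n_gained, spec.signature_enrichment, "gained")
    assign(n_lost, spec.lost_signature_enrichment, "lost")
    truth["class"] = cls

    base = rng.uniform(*spec.density_range, size=n)
    truth["base_density"] = base
    minus = base * np.where(cls == "lost", spec.planted_fold, 1.0)
    plus = base * np.where(cls == "gained", spec.planted_fold, 1.0)
    if spec.noise_cv > 0:
        s2 = np.log1p(spec.noise_cv**2)
        s = np.sqrt(s2)
        minus = minus * rng.lognormal(-s2 / 2, s, size=n)
        plus = plus * rng.lognormal(-s2 / 2, s, size=n)

    def track(values: np.ndarray) -> TagTrack:
        return TagTrack(
            pd.DataFrame(
                {
                    "chrom": CHROM,
                    "start": truth["start"].to_numpy(),
                    "end": truth["end"].to_numpy(),
                    "value": values,
                }
            )
        )

    jitter = rng.integers(-spec.summit_jitter, spec.summit_jitter + 1, size=n)
    summit = truth["summit"].to_numpy()
    start_arr = truth["start"].to_numpy()
    end_arr = truth["end"].to_numpy()
    plus_summit = np.clip(summit + jitter, start_arr, end_arr - 1)
    peaks_minus = PeakSet(
        [
            Peak(GenomicInterval(CHROM, int(s), int(e)), int(sm), f"m_{nm}")
            for s, e, sm, nm in zip(start_arr, end_arr, summit, truth["name"])
        ],
        label="minus",
    )
    peaks_plus = PeakSet(
        [
            Peak(GenomicInterval(CHROM, int(s), int(e)), int(sm), f"p_{nm}")
            for s, e, sm, nm in zip(start_arr, end_arr, plus_summit, truth["name"])
        ],
        label="plus",
    )
    return ExperimentResult(
        peaks_minus=peaks_minus,
        peaks_plus=peaks_plus,
        track_minus=track(minus),
        track_plus=track(plus),
        truth=truth,
        spec=spec,
    )


def truth_for_union(union, truth: pd.DataFrame) -> pd.Series:
    """Planted class per union peak, looked up through member peak names.

    Member names carry the ``m_``/``p_`` condition prefix added by
    :func:`simulate_experiment`; the planted class of the first member
    wins (members of one union peak share a class by construction).
    """
    by_name = truth.set_index("name")["class"]
    out = {}
    for u in union:
        src = u.members[0].split("_", 1)[1]
        out[u.name] = by_name[src]
    return pd.Series(out)


def simulate_motifs(
    peak_sets: Mapping[str, PeakSet],
    rates: Mapping[str, Mapping[str, float]],
    seed: int,
) -> tuple[MotifCounts, dict[str, list[tuple[str, int]]]]:
    """Bernoulli motif hits per peak set.

    ``rates[motif][set_label]`` is the per-peak hit probability; a peak
    carrying the motif gets one hit at a uniform position within it.
    Returns the aggregated MotifCounts and per-motif hit positions.
    """
    rng = np.random.default_rng(seed)
    set_labels = list(peak_sets)
    m = pd.Series({lab: len(peak_sets[lab]) for lab in set_labels})
    n = pd.DataFrame(0, index=list(rates), columns=set_labels)
    positions: dict[str, list[tuple[str, int]]] = {motif: [] for motif in rates}
    for motif, per_set in rates.items():
        for lab in set_labels:
            p = per_set.get(lab, 0.0)
            if not 0 <= p <= 1:
                raise ValueError("hit probabilities must lie in [0, 1]")
            carriers = rng.random(len(peak_sets[lab])) < p
            n.loc[motif, lab] = int(carriers.sum())
            for peak, c in zip(peak_sets[lab], carriers):
                if c:
                    pos = int(rng.integers(peak.start, peak.end))
                    positions[motif].append((peak.chrom, pos))
    return MotifCounts(n=n, m=m), positions


_CATEGORY_FOLDS = {
    "up_both": ("up", "up"),
    "up_minus_only": ("up", "flat"),
    "up_plus_only": ("flat", "up"),
    "down_minus_only": ("down", "flat"),
    "down_plus_only": ("flat", "down"),
    "down_both": ("down", "down"),
    "unchanged": ("flat", "flat"),
}


def simulate_de_tables(
    n_genes: int,
    mix: Mapping[str, float],
    fold_up: float = 4.0,
    fold_down: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired DE tables with planted trajectory categories.

    ``mix`` maps trajectory categories to fractions summing to 1.  Output
    fold changes are noiseless (exactly ``fold_up``/``fold_down``/1), so the
    trajectory classifier recovers the planted categories exactly.  Returns
    (minus-contrast table, plus-contrast table, planted categories).
    """
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("category mix must sum to 1")
    unknown = set(mix) - set(_CATEGORY_FOLDS)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cats = list(mix)
    counts = np.floor(np.asarray([mix[c] for c in cats]) * n_genes).astype(int)
    for i in range(n_genes - counts.sum()):  # distribute rounding remainder
        counts[i % len(counts)] += 1
    labels = np.repeat(cats, counts)
    labels = labels[rng.permutation(n_genes)]
    fold_of = {"up": fold_up, "down": fold_down, "flat": 1.0}
    genes = unique_names("gene_", n_genes)
    rows_minus, rows_plus = [], []
    for g, lab in zip(genes, labels):
        fm, fp = (fold_of[d] for d in _CATEGORY_FOLDS[lab])
        rows_minus.append((g, np.log2(fm), 0.001 if fm != 1.0 else 0.9, "minus"))
        rows_plus.append((g, np.log2(fp), 0.001 if fp != 1.0 else 0.9, "plus"))
    cols = ["gene_id", "log2fc", "adj_p", "contrast"]
    return (
        pd.DataFrame(rows_minus, columns=cols),
        pd.DataFrame(rows_plus, columns=cols),
        pd.Series(labels, index=genes, name="category"),
    )
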