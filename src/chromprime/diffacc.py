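"""Differential chromatin accessibility between paired conditions.

The workflow mirrors the standard summit-anchored recipe for comparing an
induced (+dox) and uninduced (−dox) ATAC-seq pair without replicates:

1. merge the two peak calls into a union, joining peaks whose summits lie
   within 400 bp of each other and re-deriving a union summit;
2. read the average tag density in a 400-bp window centred on each union
   summit from each condition's bedGraph track;
3. normalise each condition to counts-per-million (CPM) and log2(CPM+1),
   with promoter-proximal (within 1.5 kb of a TSS) and distal peaks
   normalised and analysed separately;
4. call a peak *gained* when the +dox/−dox pseudocounted CPM ratio is at
   least twofold, *lost* when at most half, *shared* otherwise.

Replicate-aware models are deliberately out of scope: the contrast is a
plain fold rule on normalised densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist

from .intervals import GeneAnnotation, GenomicInterval, Peak, PeakSet, nearest_tss_distance
from .tracks import TagTrack

__all__ = [
    "UnionPeak",
    "build_peak_union",
    "union_to_peakset",
    "classify_element",
    "window_tag_density",
    "cpm_log_normalize",
    "call_differential",
    "differential_table",
    "write_differential_table",
    "read_differential_table",
    "ranked_density_matrix",
    "correlation_cluster",
]

GAINED, LOST, SHARED = "gained", "lost", "shared"
PROMOTER, DISTAL = "promoter", "distal"


@dataclass(frozen=True)
class UnionPeak:
    """A merged peak: widest extent of its members, mean-of-summits anchor."""

    interval: GenomicInterval
    summit: int
    name: str
    members: tuple[str, ...]
    member_conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("union peak needs >= 1 member")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("union summit outside merged interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def build_peak_union(
    set_minus: PeakSet,
    set_plus: PeakSet,
    summit_distance: int = 400,
    name_prefix: str = "union_",
) -> list[UnionPeak]:
    """Merge two condition peak sets by summit proximity.

    Peaks whose summits lie within ``summit_distance`` bp on the same
    chromosome merge transitively (chain rule, as ``bedtools merge`` would
    chain them): sorting by summit, a new group starts whenever the gap to
    the previous summit exceeds the threshold.  The merged summit is the
    floor of the mean of all member summits — for two peaks, the midpoint
    between the original summits — and the merged interval spans min start
    to max end.  Unmerged peaks pass through with their original summits.
    """
    if summit_distance < 0:
        raise ValueError("summit_distance must be >= 0")
    tagged = [(p, "minus") for p in set_minus] + [(p, "plus") for p in set_plus]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].summit, t[0].start, t[0].name))
    groups: list[list[tuple[Peak, str]]] = []
    for peak, cond in tagged:
        if (
            groups
            and groups[-1][-1][0].chrom == peak.chrom
            and peak.summit - groups[-1][-1][0].summit <= summit_distance
        ):
            groups[-1].append((peak, cond))
        else:
            groups.append([(peak, cond)])
    width = max(1, len(str(max(len(groups) - 1, 1))))
    out = []
    for i, grp in enumerate(groups):
        peaks = [p for p, _ in grp]
        summit = int(np.floor(np.mean([p.summit for p in peaks])))
        interval = GenomicInterval(
            peaks[0].chrom,
            min(p.start for p in peaks),
            max(p.end for p in peaks),
        )
        out.append(
            UnionPeak(
                interval,
                summit,
                f"{name_prefix}{i:0{width}d}",
                tuple(p.name for p, _ in grp),
                tuple(c for _, c in grp),
            )
        )
    out.sort(key=lambda u: (u.chrom, u.interval.start, u.interval.end))
    return out


def union_to_peakset(union: Sequence[UnionPeak], label: str = "union") -> PeakSet:
    return PeakSet(
        [Peak(u.interval, u.summit, u.name) for u in union], label=label
    )


def classify_element(
    peaks: PeakSet, genes: GeneAnnotation, window: int = 1500
) -> np.ndarray:
    """Label each peak promoter-proximal (|summit − nearest TSS| <= window) or distal."""
    if len(genes) == 0:
        raise ValueError("gene table is empty")
    dist = nearest_tss_distance(peaks, genes)
    return np.where(dist <= window, PROMOTER, DISTAL)


def window_tag_density(
    track: TagTrack, chrom: str, summit: int, width: int = 400
) -> float:
    """Average tag density in a ``width`` window centred on the summit.

    The window is [summit − width/2, summit + width/2); windows truncated
    at position 0 keep the divisor at ``width`` (off-chromosome bases count
    as zero coverage).
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be positive and even")
    half = width // 2
    return track.window_mean(chrom, summit - half, summit + half, divisor=width)


def _window_densities(
    track: TagTrack, peaks: Sequence, width: int
) -> np.ndarray:
    return np.asarray(
        [window_tag_density(track, p.chrom, p.summit, width) for p in peaks]
    )


def cpm_log_normalize(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-million per column, and log2(CPM + 1).

    Each column is scaled to sum to 1e6 exactly; a zero column sum is an
    error naming the sample.
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw densities must be >= 0")
    colsums = raw.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total signal")
    cpm = raw / colsums * 1e6
    return cpm, np.log2(cpm + 1.0)


def call_differential(
    cpm: pd.DataFrame,
    minus: str = "minus",
    plus: str = "plus",
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Fold change and gained/lost/shared labels from a two-column CPM table.

    fold = (cpm_plus + 1) / (cpm_minus + 1); gained iff fold >= threshold,
    lost iff fold <= 1/threshold, shared otherwise.  The pseudocount keeps
    zero-coverage peaks well defined, and the boundary (exactly twofold)
    counts as differential.
    """
    for col in (minus, plus):
        if col not in cpm.columns:
            raise ValueError(f"condition column {col!r} missing")
    fold = (cpm[plus] + 1.0) / (cpm[minus] + 1.0)
    label = np.where(
        fold >= fold_threshold, GAINED,
        np.where(fold <= 1.0 / fold_threshold, LOST, SHARED),
    )
    return pd.DataFrame({"fold": fold, "class": label}, index=cpm.index)


def differential_table(
    union: Sequence[UnionPeak],
    track_minus: TagTrack,
    track_plus: TagTrack,
    genes: GeneAnnotation | None = None,
    width: int = 400,
    promoter_window: int = 1500,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Full differential table over a peak union.

    Promoter-proximal and distal peaks are CPM-normalised separately (each
    element class forms its own million); without a gene table every peak is
    treated as distal.  Columns: peak, chrom, start, end, summit, element,
    raw_minus, raw_plus, cpm_minus, cpm_plus, log2_minus, log2_plus, fold,
    class.
    """
    pset = union_to_peakset(union)
    if genes is not None and len(genes):
        element = classify_element(pset, genes, promoter_window)
    else:
        element = np.full(len(pset), DISTAL)
    raw = pd.DataFrame(
        {
            "minus": _window_densities(track_minus, list(pset), width),
            "plus": _window_densities(track_plus, list(pset), width),
        },
        index=[p.name for p in pset],
    )
    cpm = raw.copy()
    for elem in (PROMOTER, DISTAL):
        mask = element == elem
        if mask.any():
            sub_cpm, _ = cpm_log_normalize(raw.loc[mask])
            cpm.loc[mask] = sub_cpm
    calls = call_differential(cpm, fold_threshold=fold_threshold)
    out = pd.DataFrame(
        {
            "peak": [p.name for p in pset],
            "chrom": [p.chrom for p in pset],
            "start": [p.start for p in pset],
            "end": [p.end for p in pset],
            "summit": [p.summit for p in pset],
            "element": element,
            "raw_minus": raw["minus"].to_numpy(),
            "raw_plus": raw["plus"].to_numpy(),
            "cpm_minus": cpm["minus"].to_numpy(),
            "cpm_plus": cpm["plus"].to_numpy(),
            "log2_minus": np.log2(cpm["minus"].to_numpy() + 1.0),
            "log2_plus": np.log2(cpm["plus"].to_numpy() + 1.0),
            "fold": calls["fold"].to_numpy(),
            "class": calls["class"].to_numpy(),
        }
    )
    return out


def write_differential_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_differential_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"peak": str, "chrom": str})


def differential_peakset(table: pd.DataFrame, cls: str, label: str | None = None) -> PeakSet:
    """PeakSet of union peaks carrying a given gained/lost/shared label."""
    sub = table[table["class"] == cls]
    return PeakSet(
        [
            Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.summit), r.peak)
            for r in sub.itertuples()
        ],
        label=label or cls,
    )


def ranked_density_matrix(
    table: pd.DataFrame,
    tracks: Mapping[str, TagTrack],
    window: int = 2000,
    bin: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-track binned density matrices with one shared row order.

    Rows are union peaks ordered by descending fold change (the side-by-side
    heatmap layout); columns are ``window/bin`` bins centred on each summit.
    """
    if window % bin:
        raise ValueError("window must be divisible by bin")
    order = table.sort_values("fold", ascending=False, kind="mergesort")
    half = window // 2
    nbins = window // bin
    cols = [f"bin_{i}" for i in range(nbins)]
    out = {}
    for name, track in tracks.items():
        rows = [
            track.binned_means(r.chrom, int(r.summit) - half, int(r.summit) + half, bin)
            for r in order.itertuples()
        ]
        mat = np.vstack(rows) if rows else np.empty((0, nbins))
        out[name] = pd.DataFrame(mat, index=order["peak"].to_numpy(), columns=cols)
    return out


def correlation_cluster(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations between sample rows, plus a leaf order.

    ``matrix`` is samples × features.  The leaf order comes from
    complete-linkage agglomeration of the Euclidean distances between the
    sample vectors, which is deterministic for a fixed input ordering.
    A zero-variance sample makes its correlations undefined and is an error.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise ValueError(
            f"sample {matrix.index[flat[0]]!r} has zero variance; "
            "correlation undefined"
        )
    corr = pd.DataFrame(
        np.corrcoef(X), index=matrix.index, columns=matrix.index
    )
    order_idx = leaves_list(complete(pdist(X, metric="euclidean")))
    return corr, [str(matrix.index[i]) for i in order_idx]
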