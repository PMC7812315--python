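"""Genomic interval data model, BED-family I/O, and overlap primitives.

Coordinates are 0-based, half-open throughout (BED convention).  A *peak*
carries a single-base summit — the position of maximal signal within the
called region — which anchors every window and merge operation downstream.
Overlap always means at least one shared base (the ``bedtools intersect``
default).

Three dialects are read and written:

``bed``
    Plain BED3+ (chrom, start, end[, name, score]).  No summit column; the
    summit falls back to the interval midpoint, rounded down.
``narrowPeak``
    BED6+4; column 10 is the summit offset from ``start`` (−1 means
    "no summit", again falling back to the midpoint).
``summit-bed``
    chrom, start, end, name, summit — a minimal dialect that round-trips
    summits exactly without the narrowPeak boilerplate columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneAnnotation",
    "read_peaks",
    "write_peaks",
    "filter_blacklist",
    "intersect_count",
    "overlaps_any",
    "nearest_gene",
    "PeakFormatError",
]

UNASSIGNED = "unassigned"


class PeakFormatError(ValueError):
    """Raised when a peak file does not parse under the named dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A summit-anchored interval with a name and optional score."""

    interval: GenomicInterval
    summit: int
    name: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class PeakSet:
    """Ordered collection of peaks, sorted by (chrom, start), unique names.

    The container keeps per-chromosome numpy coordinate arrays so that the
    overlap and nearest-feature queries run as vectorised sweeps.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = "") -> None:
        peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
        names = [p.name for p in peaks]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate peak name {dup!r} in set {label!r}")
        self.peaks: list[Peak] = peaks
        self.label = label
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.peaks == other.peaks

    def chroms(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    def by_chrom(self, chrom: str) -> list[Peak]:
        return [p for p in self.peaks if p.chrom == chrom]

    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        # start/end arrays per chromosome; starts are sorted because the
        # peak list is.
        if self._index is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for p in self.peaks:
                s, e = idx.setdefault(p.chrom, ([], []))
                s.append(p.start)
                e.append(p.end)
            self._index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in idx.items()
            }
        return self._index

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "summit": [p.summit for p in self.peaks],
                "score": [p.score for p in self.peaks],
            }
        )

    def subset(self, keep: Sequence[bool] | np.ndarray, label: str | None = None) -> "PeakSet":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (len(self.peaks),):
            raise ValueError("mask length does not match peak count")
        return PeakSet(
            [p for p, k in zip(self.peaks, keep) if k],
            label if label is not None else self.label,
        )


@dataclass
class GeneAnnotation:
    """TSS-level gene annotation: one record per gene_id.

    Strand is carried for completeness but does not enter distance
    computations; distances are summit-to-TSS in genomic coordinates.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("gene_id", "chrom", "strand", "tss")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if (self.table["tss"] < 0).any():
            raise ValueError("tss positions must be >= 0")
        # sort by (chrom, tss, gene_id) so that equidistant ties resolve to
        # the lexicographically smallest gene_id deterministically
        self.table = (
            self.table.sort_values(["chrom", "tss", "gene_id"])
            .reset_index(drop=True)
        )

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        tbl = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        return cls(tbl)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.table)

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]


# ---------------------------------------------------------------------------
# I/O


def _fallback_summit(start: int, end: int) -> int:
    return (start + end) // 2


def read_peaks(path, format: str = "narrowPeak", label: str | None = None) -> PeakSet:
    """Read a peak file in one of the ``bed``/``narrowPeak``/``summit-bed`` dialects.

    Peaks lacking a summit (plain BED, or a narrowPeak summit offset of −1)
    get the interval midpoint, rounded down.  Unnamed BED3 rows are named
    ``peak_<i>`` by file order.
    """
    if format not in ("bed", "narrowPeak", "summit-bed"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                peaks.append(_parse_row(fields, format, lineno))
            except (ValueError, IndexError) as exc:
                raise PeakFormatError(
                    f"{path}, line {lineno}: {exc}"
                ) from exc
    return PeakSet(peaks, label=label if label is not None else str(path))


def _parse_row(fields: Sequence[str], format: str, lineno: int) -> Peak:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    if end <= start:
        raise ValueError(f"end {end} <= start {start}")
    score: float | None = None
    if format == "narrowPeak":
        if len(fields) < 10:
            raise ValueError(f"narrowPeak needs 10 columns, got {len(fields)}")
        name = fields[3]
        score = float(fields[4])
        offset = int(fields[9])
        summit = start + offset if offset >= 0 else _fallback_summit(start, end)
    elif format == "summit-bed":
        if len(fields) < 5:
            raise ValueError(f"summit-bed needs 5 columns, got {len(fields)}")
        name = fields[3]
        summit = int(fields[4])
    else:  # bed
        name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
        if len(fields) > 4:
            score = float(fields[4])
        summit = _fallback_summit(start, end)
    return Peak(GenomicInterval(chrom, start, end), summit, name, score)


def write_peaks(peaks: PeakSet, path, format: str = "narrowPeak") -> None:
    """Write a PeakSet; tab-separated, newline-terminated, no header."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0.0 if p.score is None else p.score
            if format == "narrowPeak":
                row = (
                    p.chrom, p.start, p.end, p.name, f"{score:g}", ".",
                    "0", "-1", "-1", p.summit - p.start,
                )
            elif format == "summit-bed":
                row = (p.chrom, p.start, p.end, p.name, p.summit)
            elif format == "bed":
                row = (p.chrom, p.start, p.end, p.name, f"{score:g}")
            else:
                raise ValueError(f"unknown peak format {format!r}")
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Overlap primitives


def _overlap_counts(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Per-query-peak number of reference peaks sharing >= 1 base.

    Sorted sweep: on each chromosome the count for query [qs, qe) equals
    #(ref starts < qe) − #(ref ends <= qs); reference ends are sorted
    separately since intervals may nest.
    """
    out = np.zeros(len(query), dtype=int)
    ref_idx = reference._chrom_index()
    for i, p in enumerate(query):
        if p.chrom not in ref_idx:
            continue
        starts, ends = ref_idx[p.chrom]
        ends_sorted = np.sort(ends)
        n_start_before = np.searchsorted(starts, p.end, side="left")
        n_end_before = np.searchsorted(ends_sorted, p.start, side="right")
        out[i] = n_start_before - n_end_before
    return out


def _overlap_counts_fast(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Vectorised variant of :func:`_overlap_counts` (same contract)."""
    out = np.zeros(len(query), dtype=int)
    ref_idx = reference._chrom_index()
    q_idx: dict[str, list[int]] = {}
    for i, p in enumerate(query):
        q_idx.setdefault(p.chrom, []).append(i)
    for chrom, rows in q_idx.items():
        if chrom not in ref_idx:
            continue
        starts, ends = ref_idx[chrom]
        ends_sorted = np.sort(ends)
        qs = np.asarray([query[i].start for i in rows])
        qe = np.asarray([query[i].end for i in rows])
        cnt = np.searchsorted(starts, qe, side="left") - np.searchsorted(
            ends_sorted, qs, side="right"
        )
        out[rows] = cnt
    return out


def overlaps_any(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Boolean mask over query peaks: True where >=1 reference peak overlaps."""
    return _overlap_counts_fast(query, reference) > 0


def intersect_count(query: PeakSet, reference: PeakSet) -> int:
    """Number of query peaks overlapping at least one reference peak.

    A query peak overlapping several reference peaks counts once.
    """
    return int(overlaps_any(query, reference).sum())


def filter_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop peaks sharing >= 1 base with any blacklist interval."""
    if len(blacklist) == 0:
        return peaks
    return peaks.subset(~overlaps_any(peaks, blacklist))


def nearest_gene(
    peaks: PeakSet, genes: GeneAnnotation
) -> dict[str, tuple[str, int | None]]:
    """Map each peak name to its nearest gene by summit-to-TSS distance.

    Returns ``{peak_name: (gene_id, signed_distance)}`` with distance
    ``summit − tss``; minimal |distance| wins, ties break to the
    lexicographically smallest gene_id.  Peaks on chromosomes without genes
    map to ``("unassigned", None)``.
    """
    result: dict[str, tuple[str, int | None]] = {}
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in genes.table.groupby("chrom", sort=False):
        per_chrom[chrom] = (
            grp["tss"].to_numpy(),
            grp["gene_id"].to_numpy(),
        )
    for p in peaks:
        if p.chrom not in per_chrom:
            result[p.name] = (UNASSIGNED, None)
            continue
        tss, gid = per_chrom[p.chrom]
        j = np.searchsorted(tss, p.summit)
        # candidates straddle the insertion point; widen to absorb ties in
        # tss position (table is sorted by tss then gene_id)
        lo, hi = max(j - 1, 0), min(j + 1, len(tss) - 1)
        cand = range(lo, hi + 1)
        best = min(cand, key=lambda k: (abs(p.summit - int(tss[k])), str(gid[k])))
        # equidistant genes at distinct tss (one left, one right) and
        # same-tss runs: scan all candidates at the minimal distance
        dmin = abs(p.summit - int(tss[best]))
        eq = np.flatnonzero(np.abs(tss.astype(np.int64) - p.summit) == dmin)
        best_gid = min(str(gid[k]) for k in eq)
        best_tss = int(tss[[k for k in eq if str(gid[k]) == best_gid][0]])
        result[p.name] = (best_gid, p.summit - best_tss)
    return result


def nearest_tss_distance(peaks: PeakSet, genes: GeneAnnotation) -> np.ndarray:
    """Absolute summit-to-nearest-TSS distance per peak (inf where no genes)."""
    mapping = nearest_gene(peaks, genes)
    return np.asarray(
        [
            np.inf if mapping[p.name][1] is None else abs(mapping[p.name][1])
            for p in peaks
        ],
        dtype=float,
    )


def unique_names(prefix: str, n: int) -> list[str]:
    """Zero-padded systematic peak names, stable across runs."""
    width = max(1, len(str(n - 1)) if n else 1)
    return [f"{prefix}{i:0{width}d}" for i in range(n)]
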