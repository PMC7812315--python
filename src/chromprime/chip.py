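"""Integration of ChIP-seq peak sets with the open-chromatin landscape.

ChIP peaks are first restricted to open chromatin (any-base overlap with an
ATAC peak).  Differential binding then reuses the accessibility fold rule,
reading tag densities in a mark-specific window centred on the ATAC union
summit — 400 bp for point-source factors, 800 bp for broad marks such as
H3K27ac so that signal on the flanking nucleosomes is counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffacc import UnionPeak, differential_table
from .intervals import PeakSet, overlaps_any
from .tracks import TagTrack

__all__ = [
    "MarkConfig",
    "filter_to_open_chromatin",
    "differential_chip",
    "average_profile",
    "shared_specific_sets",
    "tf_target_fraction",
]

DEFAULT_MARKS = {
    "default": {"window": 400, "broad": False},
    "H3K27ac": {"window": 800, "broad": True},
}


@dataclass(frozen=True)
class MarkConfig:
    """Per-mark tag-density window; broad marks use a wide, flank-counting one."""

    name: str = "default"
    window: int = 400
    broad: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2:
            raise ValueError("window must be positive and even")

    @classmethod
    def from_mapping(cls, marks: Mapping[str, Mapping], name: str) -> "MarkConfig":
        cfg = marks.get(name, marks.get("default", {}))
        return cls(
            name=name,
            window=int(cfg.get("window", 400)),
            broad=bool(cfg.get("broad", False)),
        )


def filter_to_open_chromatin(chip: PeakSet, atac: PeakSet) -> PeakSet:
    """Retain ChIP peaks overlapping >= 1 ATAC peak by >= 1 base."""
    if len(atac) == 0:
        return chip.subset(np.zeros(len(chip), dtype=bool))
    return chip.subset(overlaps_any(chip, atac))


def differential_chip(
    minus_track: TagTrack,
    plus_track: TagTrack,
    union_peaks: Sequence[UnionPeak],
    cfg: MarkConfig = MarkConfig(),
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Differential ChIP signal over ATAC union peaks.

    Same contract as the accessibility differential table (shared code
    path), with densities read in ``cfg.window`` centred on the ATAC union
    summit — for broad marks this deliberately counts flanking signal.
    """
    return differential_table(
        union_peaks,
        minus_track,
        plus_track,
        genes=None,
        width=cfg.window,
        fold_threshold=fold_threshold,
    )


def average_profile(
    track: TagTrack,
    reference_summits: Sequence[tuple[str, int]],
    window: int = 4000,
    bin: int = 10,
) -> np.ndarray:
    """Mean binned density across reference points (length window/bin)."""
    if window % bin:
        raise ValueError("window must be divisible by bin")
    if not reference_summits:
        raise ValueError("no reference summits")
    half = window // 2
    rows = [
        track.binned_means(chrom, summit - half, summit + half, bin)
        for chrom, summit in reference_summits
    ]
    return np.vstack(rows).mean(axis=0)


def shared_specific_sets(
    sets: Mapping[str, PeakSet], base: str
) -> dict[tuple[str, ...], int]:
    """UpSet-style exclusive combination counts for a designated base set.

    Each base peak is assigned to exactly the combination of other sets it
    overlaps (base itself always included), so the counts partition the base
    set and sum to its size.  Keys are sorted label tuples; the base-only
    combination is ``(base,)``.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 peak sets")
    if base not in sets:
        raise ValueError(f"base set {base!r} not among inputs")
    base_set = sets[base]
    others = [k for k in sets if k != base]
    masks = {k: overlaps_any(base_set, sets[k]) for k in others}
    counts: dict[tuple[str, ...], int] = {}
    for i in range(len(base_set)):
        combo = tuple(sorted([base] + [k for k in others if masks[k][i]]))
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def tf_target_fraction(
    de_genes: Mapping[str, set],
    factor_targets: Mapping[tuple[str, str], set],
) -> pd.DataFrame:
    """Percentage of de-regulated genes bound by each factor/change combination.

    ``de_genes`` maps a direction ("up"/"down") to its gene set;
    ``factor_targets`` maps (factor, binding-change label) — e.g.
    ("RUNX1", "lost") — to the genes nearest such a site.  For every
    direction, each factor's label percentages plus an "unbound" remainder
    sum to exactly 100.  Empty direction sets are flagged absent.
    """
    rows = []
    factors = sorted({f for f, _ in factor_targets})
    for direction, genes in de_genes.items():
        n = len(genes)
        if n == 0:
            rows.append(
                {"direction": direction, "factor": None, "label": None,
                 "percent": np.nan, "n_genes": 0, "absent": True}
            )
            continue
        for factor in factors:
            bound = set()
            for (f, label), targets in sorted(factor_targets.items()):
                if f != factor:
                    continue
                hit = genes & targets
                bound |= hit
                rows.append(
                    {"direction": direction, "factor": factor, "label": label,
                     "percent": 100.0 * len(hit) / n, "n_genes": len(hit),
                     "absent": False}
                )
            rows.append(
                {"direction": direction, "factor": factor, "label": "unbound",
                 "percent": 100.0 * (n - len(bound)) / n,
                 "n_genes": n - len(bound), "absent": False}
            )
    return pd.DataFrame(rows)
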