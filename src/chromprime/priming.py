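"""Lineage-priming enrichment by matched-size random resampling.

Chromatin priming — accessible regulatory regions of a mature lineage
already present in a progenitor — is quantified here by asking whether a
set of condition-specific differential peaks overlaps a cell-type-specific
signature more (or less) often than size-matched random draws from the full
distal peak universe.

For a test set of size n drawn against a signature:

* x  = number of test peaks overlapping >= 1 signature peak;
* each of ``n_resamples`` draws takes n distinct peaks uniformly without
  replacement from the universe and records its overlap count;
* z = (x − μ)/σ with μ, σ the mean and population SD of those counts;
* p_enrich = proportion of resample counts strictly greater than x (low
  value ⇒ enrichment), p_deplete analogously with strictly less.

Because draws are uniform without replacement, the resample count is
exactly hypergeometric in (|universe|, #signature-overlapping universe
peaks, n) — the closed form used as the independent oracle in the tests.
Signatures themselves come from replicated mature-cell peak sets: a peak is
reproducible if found in every replicate of its cell type, and specific if
it additionally overlaps no other cell type's reproducible peaks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet, intersect_count, overlaps_any

__all__ = [
    "SignatureAtlas",
    "PrimingResult",
    "derive_signatures",
    "priming_test",
    "priming_panel",
    "subseed",
]


@dataclass
class SignatureAtlas:
    """Per-cell-type exclusive peak sets plus replicate provenance."""

    signatures: dict[str, PeakSet]
    replicate_counts: dict[str, int] = field(default_factory=dict)

    def cell_types(self) -> list[str]:
        return sorted(self.signatures)

    def __getitem__(self, cell_type: str) -> PeakSet:
        return self.signatures[cell_type]


@dataclass(frozen=True)
class PrimingResult:
    """Observed overlap, resampling null moments, Z-score and empirical tails."""

    x: int
    mu: float
    sigma: float
    z: float | None
    p_enrich: float
    p_deplete: float
    n_resamples: int
    seed: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "x": self.x, "mu": self.mu, "sigma": self.sigma,
            "z": np.nan if self.z is None else self.z,
            "p_enrich": self.p_enrich, "p_deplete": self.p_deplete,
            "n_resamples": self.n_resamples, "seed": self.seed,
            "degenerate": self.degenerate,
        }


def derive_signatures(
    replicated_sets: Mapping[str, Sequence[PeakSet]],
) -> SignatureAtlas:
    """Cell-type-specific signatures from replicated peak sets.

    Per cell type, the reproducible peaks are those of replicate 1 that
    overlap every other replicate; the signature keeps the reproducible
    peaks with zero overlap against the union of all *other* cell types'
    reproducible peaks.  Signatures are therefore pairwise disjoint in the
    sense that no peak region is claimed by two cell types.
    """
    if len(replicated_sets) < 2:
        raise ValueError("specificity needs >= 2 cell types")
    reproducible: dict[str, PeakSet] = {}
    for cell_type, reps in replicated_sets.items():
        if not reps:
            raise ValueError(f"cell type {cell_type!r} has no replicates")
        keep = np.ones(len(reps[0]), dtype=bool)
        for other in reps[1:]:
            keep &= overlaps_any(reps[0], other)
        reproducible[cell_type] = reps[0].subset(keep, label=f"{cell_type}_reproducible")
    signatures = {}
    for cell_type, rep in reproducible.items():
        # peak names can collide across cell types; rebuild with unique names
        other_union = _renamed_union(
            [ps for ct, ps in reproducible.items() if ct != cell_type]
        )
        mask = (
            ~overlaps_any(rep, other_union)
            if len(other_union)
            else np.ones(len(rep), dtype=bool)
        )
        signatures[cell_type] = rep.subset(mask, label=f"{cell_type}_signature")
    return SignatureAtlas(
        signatures=signatures,
        replicate_counts={ct: len(reps) for ct, reps in replicated_sets.items()},
    )


def _renamed_union(sets: Sequence[PeakSet]) -> PeakSet:
    from .intervals import Peak

    peaks = []
    for i, ps in enumerate(sets):
        for p in ps:
            peaks.append(Peak(p.interval, p.summit, f"s{i}_{p.name}", p.score))
    return PeakSet(peaks, label="union")


def priming_test(
    test_peaks: PeakSet,
    universe: PeakSet,
    signature: PeakSet,
    n_resamples: int = 1000,
    seed: int = 0,
    smoothed: bool = False,
) -> PrimingResult:
    """Matched-size uniform resampling test of signature overlap.

    Draws ``n_resamples`` sets of ``len(test_peaks)`` distinct peaks from
    ``universe`` (which must contain the test peaks) and compares the
    observed overlap count x against the resampled counts.  σ is the
    population SD of the counts; σ = 0 (signature covering everything or
    nothing) yields a degenerate result with z = None rather than ±inf.
    Empirical p-values use strict inequalities; ``smoothed`` switches to the
    +1-smoothed variant (#{count >= x} + 1)/(n + 1) for users needing p > 0.
    """
    n = len(test_peaks)
    N = len(universe)
    if n > N:
        raise ValueError("test set larger than universe")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    universe_names = {p.name for p in universe}
    test_names = {p.name for p in test_peaks}
    if not test_names <= universe_names:
        # fall back to exact interval identity
        uni_keys = {(p.chrom, p.start, p.end) for p in universe}
        if not all((p.chrom, p.start, p.end) in uni_keys for p in test_peaks):
            raise ValueError("test peaks must be a subset of the universe")
    x = intersect_count(test_peaks, signature)
    hit = overlaps_any(universe, signature)  # bool per universe peak
    rng = np.random.default_rng(seed)
    counts = _resample_counts(hit, n, n_resamples, rng)
    mu = float(counts.mean())
    sigma = float(counts.std())  # population SD (ddof=0)
    if smoothed:
        p_enrich = (int((counts >= x).sum()) + 1) / (n_resamples + 1)
        p_deplete = (int((counts <= x).sum()) + 1) / (n_resamples + 1)
    else:
        p_enrich = float((counts > x).mean())
        p_deplete = float((counts < x).mean())
    degenerate = sigma == 0.0
    z = None if degenerate else (x - mu) / sigma
    return PrimingResult(
        x=x, mu=mu, sigma=sigma, z=z,
        p_enrich=float(p_enrich), p_deplete=float(p_deplete),
        n_resamples=n_resamples, seed=seed, degenerate=degenerate,
    )


def _resample_counts(
    hit: np.ndarray, n: int, n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Overlap counts of ``n_resamples`` without-replacement draws of size n.

    Each row of a tiled copy of the universe's hit mask is independently
    permuted; the first n entries of a permuted row are a uniform draw of n
    distinct peaks.
    """
    N = len(hit)
    if n == 0:
        return np.zeros(n_resamples, dtype=int)
    # chunk to bound memory at ~32 MB of bools
    chunk = max(1, int(32e6 // max(N, 1)))
    counts = np.empty(n_resamples, dtype=int)
    done = 0
    while done < n_resamples:
        k = min(chunk, n_resamples - done)
        tiled = np.tile(hit, (k, 1))
        tiled = rng.permuted(tiled, axis=1)
        counts[done : done + k] = tiled[:, :n].sum(axis=1)
        done += k
    return counts


def subseed(master_seed: int, *parts: str) -> int:
    """Deterministic per-test sub-seed below 2**31.

    Hashes (master seed, label parts) so adding a test never perturbs the
    draws of another.
    """
    h = hashlib.sha256(
        ("\x1f".join([str(master_seed), *parts])).encode()
    ).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def priming_panel(
    differential: pd.DataFrame,
    atlas: SignatureAtlas,
    n_resamples: int = 1000,
    seed: int = 0,
    condition: str = "condition",
    classes: Sequence[str] = ("gained", "lost"),
    element: str = "distal",
) -> pd.DataFrame:
    """Run the priming test for each differential class × cell type.

    ``differential`` is the accessibility differential table; only rows of
    the requested element class form the universe (all distal union peaks),
    and the gained and lost subsets are the test sets.  Each test gets a
    deterministic sub-seed from the master seed and its labels.  Empty test
    sets yield a flagged absent row rather than a result.
    """
    from .intervals import GenomicInterval, Peak

    sub = differential[differential["element"] == element]
    # universe = every distal union peak regardless of class
    universe = PeakSet(
        [
            Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.summit), r.peak)
            for r in sub.itertuples()
        ],
        label="universe",
    )
    rows = []
    for cls in classes:
        cls_tbl = sub[sub["class"] == cls]
        test = PeakSet(
            [
                Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), int(r.summit), r.peak)
                for r in cls_tbl.itertuples()
            ],
            label=cls,
        )
        for cell_type in atlas.cell_types():
            base = {"condition": condition, "class": cls, "cell_type": cell_type}
            if len(test) == 0:
                rows.append({**base, "absent": True})
                continue
            s = subseed(seed, condition, cls, cell_type)
            res = priming_test(
                test, universe, atlas[cell_type], n_resamples=n_resamples, seed=s
            )
            rows.append({**base, "absent": False, **res.as_dict()})
    return pd.DataFrame(rows)
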