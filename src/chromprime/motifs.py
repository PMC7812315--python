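"""Motif enrichment scoring over peak sets.

For motif *i* and peak set *j* with hit count ``n_ij`` out of ``m_j`` sites,
the enrichment score is the set-level motif frequency relative to the
pooled frequency across all sets::

    S_ij = (n_ij / m_j) / (sum_j n_ij / sum_j m_j)

S = 1 means the motif occurs at the pooled background rate; the scores obey
the weighted-mean identity sum_j m_j * S_ij / sum_j m_j = 1 for every motif,
and are invariant to scaling all counts and set sizes by a constant.  Where
hits come from (a PWM scanner, a de-novo search) is out of scope — any
binary per-peak hit table aggregates to the counts this module consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist

__all__ = [
    "MotifCounts",
    "enrichment_scores",
    "cluster_scores",
    "motif_density_matrix",
    "counts_from_hit_table",
    "read_motif_counts",
    "write_score_matrix",
]


@dataclass
class MotifCounts:
    """Hit counts ``n`` (motifs × peak sets) and set sizes ``m`` (per set)."""

    n: pd.DataFrame
    m: pd.Series

    def __post_init__(self) -> None:
        self.m = self.m.reindex(self.n.columns)
        if self.m.isna().any():
            missing = self.m.index[self.m.isna()][0]
            raise ValueError(f"no set size for peak set {missing!r}")
        if (self.m <= 0).any():
            bad = self.m.index[self.m <= 0][0]
            raise ValueError(f"peak set {bad!r} has size m_j = 0")
        if (self.n.to_numpy() < 0).any():
            raise ValueError("hit counts must be >= 0")
        if (self.n.gt(self.m, axis=1)).any().any():
            raise ValueError("hit count n_ij exceeds set size m_j")


def enrichment_scores(counts: MotifCounts) -> pd.DataFrame:
    """Score matrix S (motifs × peak sets).

    Motifs observed in no set (sum_j n_ij = 0) would give 0/0 and are
    dropped with a warning.
    """
    n, m = counts.n, counts.m.astype(float)
    observed = n.sum(axis=1) > 0
    if not observed.all():
        dropped = list(n.index[~observed])
        warnings.warn(f"dropping motifs observed in no set: {dropped}")
        n = n.loc[observed]
    pooled_rate = n.sum(axis=1) / m.sum()
    per_set_rate = n.div(m, axis=1)
    return per_set_rate.div(pooled_rate, axis=0)


def cluster_scores(S: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Deterministic complete-linkage/Euclidean leaf orders (rows, columns).

    Ties follow the agglomeration sequence over the input ordering; a single
    row or column yields the trivial ordering.
    """
    if S.shape[0] < 1:
        raise ValueError("empty score matrix")

    def order(mat: np.ndarray, labels) -> list[str]:
        if mat.shape[0] < 2:
            return [str(x) for x in labels]
        idx = leaves_list(complete(pdist(mat, metric="euclidean")))
        return [str(labels[i]) for i in idx]

    X = S.to_numpy(dtype=float)
    return order(X, S.index), order(X.T, S.columns)


def motif_density_matrix(
    hits: dict[str, list[tuple[str, int]]] | list[tuple[str, int]],
    summits: list[tuple[str, int]],
    window: int = 2000,
    bin: int = 10,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Motif hit counts per summit-relative bin.

    ``hits`` is a list of (chrom, position) match positions (or a mapping
    motif → such a list, returning one matrix per motif); rows are reference
    summits, columns the ``window/bin`` bins of the half-open window
    [summit − window/2, summit + window/2).
    """
    if isinstance(hits, dict):
        return {k: motif_density_matrix(v, summits, window, bin) for k, v in hits.items()}
    if window % bin:
        raise ValueError("window must be divisible by bin")
    nbins = window // bin
    half = window // 2
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in hits:
        if pos < 0:
            raise ValueError("hit positions must be >= 0")
        by_chrom.setdefault(chrom, [])
    for chrom, pos in hits:
        by_chrom[chrom].append(pos)
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    mat = np.zeros((len(summits), nbins), dtype=int)
    for r, (chrom, summit) in enumerate(summits):
        positions = by_chrom.get(chrom)
        if positions is None:
            continue
        rel = positions - (summit - half)
        inside = rel[(rel >= 0) & (rel < window)]
        if len(inside):
            mat[r] = np.bincount(inside // bin, minlength=nbins)
    return pd.DataFrame(
        mat,
        index=[f"ref_{i}" for i in range(len(summits))],
        columns=[f"bin_{i}" for i in range(nbins)],
    )


def counts_from_hit_table(hits: pd.DataFrame) -> MotifCounts:
    """Aggregate a per-peak binary hit table to MotifCounts.

    ``hits`` columns: peak set label ("set"), peak name ("peak"), then one
    0/1 column per motif.  m_j is the number of distinct peaks per set.
    """
    for col in ("set", "peak"):
        if col not in hits.columns:
            raise ValueError(f"hit table missing column {col!r}")
    motif_cols = [c for c in hits.columns if c not in ("set", "peak")]
    grouped = hits.groupby("set")
    n = grouped[motif_cols].sum().T  # motifs × sets
    m = grouped["peak"].nunique()
    return MotifCounts(n=n, m=m)


def read_motif_counts(path) -> MotifCounts:
    """Read long-format TSV (motif, set, n, m) into MotifCounts."""
    tbl = pd.read_csv(path, sep="\t", dtype={"motif": str, "set": str})
    n = tbl.pivot(index="motif", columns="set", values="n").fillna(0).astype(int)
    m = tbl.groupby("set")["m"].first()
    return MotifCounts(n=n, m=m)


def write_score_matrix(S: pd.DataFrame, path, zscore_rows: bool = False) -> None:
    """Write the score matrix as headered TSV; optionally per-row z-scored.

    The z-scored variant is a display transform only and is labelled as
    such in the column index name.
    """
    out = S
    if zscore_rows:
        out = S.sub(S.mean(axis=1), axis=0).div(S.std(axis=1), axis=0)
        out.columns.name = "row_zscore"
    out.to_csv(path, sep="\t", index_label="motif")
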