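"""Downstream classification and overlap arithmetic on differential-expression tables.

Operates on precomputed per-contrast tables of (gene, log2 fold change,
adjusted p); fitting the expression model itself is out of scope.  A gene is
de-regulated at |fold| >= 2 — combined with adjusted p < 0.05 when the table
carries one — matching the convention used throughout.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffacc import correlation_cluster

__all__ = [
    "TRAJECTORY_CATEGORIES",
    "filter_expressed",
    "classify_trajectory",
    "trajectory_tallies",
    "deregulated_sets",
    "pairwise_overlap",
    "fold_change_correlation",
    "read_de_table",
]

TRAJECTORY_CATEGORIES = (
    "up_both",
    "up_minus_only",
    "up_plus_only",
    "down_minus_only",
    "down_plus_only",
    "down_both",
    "unchanged",
)


def filter_expressed(counts: pd.DataFrame, min_reads: int = 50) -> pd.Index:
    """Genes with at least ``min_reads`` in at least one sample.

    ``counts`` is genes × samples of non-negative integers.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("read counts must be >= 0")
    if len(counts) == 0:
        return counts.index
    return counts.index[counts.max(axis=1) >= min_reads]


def _direction(fold: float, threshold: float) -> str:
    if fold >= threshold:
        return "up"
    if fold <= 1.0 / threshold:
        return "down"
    return "none"


def classify_trajectory(
    fc_minus: float, fc_plus: float, threshold: float = 2.0
) -> str:
    """One of the seven trajectory categories for a (−dox, +dox) fold pair.

    Folds are linear and must be positive; up means fold >= threshold, down
    means fold <= 1/threshold.  Concordant pairs map to up_both/down_both,
    a change in exactly one condition to the respective "-only" class, and
    neither to unchanged.  Discordant pairs (up in one condition, down in
    the other) are assigned to the condition with the larger |log2 fold|,
    ties going to the up-regulated condition — a rule chosen so the map is
    exhaustive, exclusive, and exactly symmetric under swapping conditions.
    Figure-style tallies that count discordant genes in both "-only" bins
    are available from :func:`trajectory_tallies`.
    """
    if fc_minus <= 0 or fc_plus <= 0:
        raise ValueError("fold changes must be positive")
    dm, dp = _direction(fc_minus, threshold), _direction(fc_plus, threshold)
    if dm == dp:
        return {"up": "up_both", "down": "down_both", "none": "unchanged"}[dm]
    if dm == "none":
        return f"{dp}_plus_only"
    if dp == "none":
        return f"{dm}_minus_only"
    # discordant: stronger |log2 fold| wins; tie -> the up direction
    if abs(np.log2(fc_minus)) > abs(np.log2(fc_plus)):
        return f"{dm}_minus_only"
    if abs(np.log2(fc_plus)) > abs(np.log2(fc_minus)):
        return f"{dp}_plus_only"
    return "up_minus_only" if dm == "up" else "up_plus_only"


def trajectory_tallies(
    fc_minus: Sequence[float],
    fc_plus: Sequence[float],
    threshold: float = 2.0,
    discordant_in_both: bool = True,
) -> pd.Series:
    """Per-category gene counts over paired fold vectors.

    With ``discordant_in_both`` (default), a gene up in one condition and
    down in the other is counted in both respective "-only" bins, so the
    tallies can exceed the number of genes; with it off, each gene counts
    once under its :func:`classify_trajectory` category.
    """
    tally = {c: 0 for c in TRAJECTORY_CATEGORIES}
    for a, b in zip(fc_minus, fc_plus):
        if a <= 0 or b <= 0:
            raise ValueError("fold changes must be positive")
        da, db = _direction(a, threshold), _direction(b, threshold)
        if discordant_in_both and "none" not in (da, db) and da != db:
            tally[f"{da}_minus_only"] += 1
            tally[f"{db}_plus_only"] += 1
        else:
            tally[classify_trajectory(a, b, threshold)] += 1
    return pd.Series(tally)


def deregulated_sets(
    table: pd.DataFrame,
    fold_threshold: float = 2.0,
    adj_p: float | None = 0.05,
) -> tuple[set, set]:
    """(up, down) gene sets from a DE table (gene_id, log2fc[, adj_p]).

    Uses |fold| >= threshold alone when the table has no adj_p column;
    otherwise requires adjusted p below the cutoff as well.
    """
    lfc = np.log2(fold_threshold)
    sig = np.ones(len(table), dtype=bool)
    if adj_p is not None and "adj_p" in table.columns:
        p = table["adj_p"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adj_p must lie in [0, 1]")
        sig = p < adj_p
    up = set(table.loc[sig & (table["log2fc"] >= lfc), "gene_id"])
    down = set(table.loc[sig & (table["log2fc"] <= -lfc), "gene_id"])
    return up, down


def pairwise_overlap(
    de_sets: Mapping[str, tuple[set, set]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Concordant and opposing overlap matrices across contrasts.

    concordant[i, j] = |up_i ∩ up_j| + |down_i ∩ down_j| (symmetric);
    opposing[i, j] = |up_i ∩ down_j| (generally asymmetric).  The third
    return is a boolean frame flagging rows/columns whose contrast has no
    de-regulated genes at all (the "greyed out" rows of the figure-style
    table).
    """
    labels = list(de_sets)
    if len(labels) < 2:
        raise ValueError("need >= 2 contrasts")
    conc = pd.DataFrame(0, index=labels, columns=labels)
    opp = pd.DataFrame(0, index=labels, columns=labels)
    for a in labels:
        ua, da = de_sets[a]
        for b in labels:
            ub, db = de_sets[b]
            conc.loc[a, b] = len(ua & ub) + len(da & db)
            opp.loc[a, b] = len(ua & db)
    empty = pd.Series(
        {lab: len(de_sets[lab][0]) + len(de_sets[lab][1]) == 0 for lab in labels}
    )
    flags = pd.DataFrame(
        np.logical_or.outer(empty.to_numpy(), empty.to_numpy()),
        index=labels, columns=labels,
    )
    return conc, opp, flags


def fold_change_correlation(
    tables: Mapping[str, pd.DataFrame],
    fold_threshold: float = 2.0,
    adj_p: float | None = 0.05,
    drop_missing: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Correlation + clustering of per-contrast fold changes over de-regulated genes.

    The feature space is the union of genes de-regulated in any contrast;
    genes missing from a contrast's table are imputed log2fc = 0 (or dropped
    from the union entirely with ``drop_missing``).  Delegates to
    :func:`chromprime.diffacc.correlation_cluster`.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 contrasts")
    universe: set = set()
    for tbl in tables.values():
        up, down = deregulated_sets(tbl, fold_threshold, adj_p)
        universe |= up | down
    if not universe:
        raise ValueError("no de-regulated genes in any contrast")
    if drop_missing:
        for tbl in tables.values():
            universe &= set(tbl["gene_id"])
    genes = sorted(universe)
    mat = pd.DataFrame(
        {
            label: tbl.set_index("gene_id")["log2fc"].reindex(genes).fillna(0.0)
            for label, tbl in tables.items()
        }
    ).T
    return correlation_cluster(mat)


def read_de_table(path) -> pd.DataFrame:
    tbl = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in tbl.columns or "log2fc" not in tbl.columns:
        raise ValueError("DE table needs gene_id and log2fc columns")
    return tbl
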