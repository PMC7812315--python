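"""Peak-union construction, normalisation and differential calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from chromprime.diffacc import (
    build_peak_union,
    call_differential,
    classify_element,
    correlation_cluster,
    cpm_log_normalize,
    differential_table,
    ranked_density_matrix,
    window_tag_density,
)
from chromprime.intervals import PeakSet
from chromprime.tracks import TagTrack

from conftest import make_peaks


def constant_track(value, chrom="chr1", end=1_000_000):
    return TagTrack(
        pd.DataFrame({"chrom": [chrom], "start": [0], "end": [end], "value": [value]})
    )


class TestPeakUnion:
    def test_two_summits_within_threshold_merge_at_midpoint(self):
        minus = make_peaks([("chr1", 0, 200, 100, "m0")], "minus")
        plus = make_peaks([("chr1", 350, 550, 450, "p0")], "plus")
        union = build_peak_union(minus, plus)
        assert len(union) == 1
        assert union[0].summit == 275
        assert (union[0].interval.start, union[0].interval.end) == (0, 550)

    def test_gap_beyond_threshold_keeps_peaks_separate(self):
        minus = make_peaks([("chr1", 0, 200, 100, "m0")], "minus")
        plus = make_peaks([("chr1", 500, 700, 600, "p0")], "plus")
        union = build_peak_union(minus, plus)
        assert len(union) == 2
        assert [u.summit for u in union] == [100, 600]

    def test_chain_merge_uses_mean_of_all_members(self):
        minus = make_peaks(
            [("chr1", 0, 200, 100, "m0"), ("chr1", 700, 900, 800, "m1")], "minus"
        )
        plus = make_peaks([("chr1", 350, 550, 450, "p0")], "plus")
        union = build_peak_union(minus, plus)
        assert len(union) == 1
        assert union[0].summit == 450  # floor(mean(100, 450, 800))

    def test_negative_distance_rejected(self):
        ps = make_peaks([("chr1", 0, 200, 100)])
        with pytest.raises(ValueError):
            build_peak_union(ps, PeakSet([], "plus"), summit_distance=-1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_transitive_closure(self, seed):
        """Sweep merge equals all-pairs transitive closure, gaps near 400 bp."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        gaps = rng.normal(400, 150, size=n).clip(10).astype(int)
        summits = np.cumsum(gaps) + 1000
        rows, cond = [], []
        for i, s in enumerate(summits):
            rows.append(("chr1", int(s) - 50, int(s) + 50, int(s), f"pk{i}"))
            cond.append(rng.random() < 0.5)
        all_peaks = make_peaks(rows, "all")
        minus = all_peaks.subset([c for c in cond], "minus")
        plus = all_peaks.subset([not c for c in cond], "plus")
        union = build_peak_union(minus, plus)
        # oracle: connected components of |summit_i − summit_j| <= 400
        adj = np.abs(summits[:, None] - summits[None, :]) <= 400
        ncomp, labels = connected_components(csr_matrix(adj), directed=False)
        assert len(union) == ncomp
        expected = sorted(
            int(np.floor(summits[labels == c].mean())) for c in range(ncomp)
        )
        assert sorted(u.summit for u in union) == expected


class TestElementClassification:
    def test_boundary_inclusive_at_window(self, gene_table):
        ps = make_peaks(
            [("chr1", 5_400, 5_600, 5_500, "at"), ("chr1", 5_450, 5_650, 5_501, "out")]
        )
        labels = classify_element(ps, gene_table, window=1500)
        assert list(labels) == ["promoter", "distal"]  # 1500 vs 1501 from geneA

    def test_no_genes_on_chromosome_is_distal(self, gene_table):
        ps = make_peaks([("chrX", 0, 200, 100, "p")])
        assert list(classify_element(ps, gene_table)) == ["distal"]


class TestWindowDensity:
    def test_constant_track(self):
        assert window_tag_density(constant_track(3.0), "chr1", 5_000) == pytest.approx(3.0)

    def test_half_and_half_window_averages(self):
        track = TagTrack(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [0, 5_000], "end": [5_000, 10_000],
                 "value": [2.0, 4.0]}
            )
        )
        assert window_tag_density(track, "chr1", 5_000) == pytest.approx(3.0)

    def test_no_coverage_is_zero(self):
        assert window_tag_density(constant_track(1.0), "chr2", 500) == 0.0

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            window_tag_density(constant_track(1.0), "chr1", 500, width=401)


class TestNormalisation:
    def test_proportional_scaling(self):
        raw = pd.DataFrame({"s1": [5.0, 5.0]})
        cpm, _ = cpm_log_normalize(raw)
        assert list(cpm["s1"]) == [500_000.0, 500_000.0]

    def test_log2_of_half_million_cpm(self):
        raw = pd.DataFrame({"s1": [5.0, 5.0]})
        _, log2 = cpm_log_normalize(raw)
        assert log2["s1"][0] == pytest.approx(18.93157, abs=1e-4)

    def test_zero_column_names_sample(self):
        with pytest.raises(ValueError, match="s2"):
            cpm_log_normalize(pd.DataFrame({"s1": [1.0], "s2": [0.0]}))

    def test_column_sums_equal_one_million(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.uniform(0, 100, size=(500, 4)), columns=list("abcd"))
        cpm, log2 = cpm_log_normalize(raw)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)
        # log transform is monotone in cpm
        order = np.argsort(cpm["a"].to_numpy())
        assert (np.diff(log2["a"].to_numpy()[order]) >= 0).all()


class TestDifferentialCalls:
    @pytest.mark.parametrize(
        "cm,cp,expected",
        [(10, 40, "gained"), (30, 20, "shared"), (50, 20, "lost"), (1, 3, "gained")],
    )
    def test_pseudocounted_fold_rule(self, cm, cp, expected):
        cpm = pd.DataFrame({"minus": [float(cm)], "plus": [float(cp)]})
        out = call_differential(cpm)
        assert out["fold"][0] == pytest.approx((cp + 1) / (cm + 1))
        assert out["class"][0] == expected

    def test_exact_twofold_boundary_is_differential(self):
        cpm = pd.DataFrame({"minus": [9.0], "plus": [19.0]})  # fold exactly 2
        assert call_differential(cpm)["class"][0] == "gained"

    def test_swapping_conditions_swaps_gained_and_lost(self):
        rng = np.random.default_rng(1)
        cpm = pd.DataFrame(
            {"minus": rng.uniform(0, 100, 300), "plus": rng.uniform(0, 100, 300)}
        )
        fwd = call_differential(cpm)["class"]
        rev = call_differential(
            cpm.rename(columns={"minus": "plus", "plus": "minus"})
        )["class"]
        swap = {"gained": "lost", "lost": "gained", "shared": "shared"}
        assert list(rev) == [swap[c] for c in fwd]


class TestRankedMatrix:
    def test_rows_ordered_by_descending_fold_and_200_bins(self):
        minus = make_peaks(
            [("chr1", 4_000, 4_400, 4_200, "m0"), ("chr1", 9_000, 9_400, 9_200, "m1")],
            "minus",
        )
        track_m = TagTrack(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [4_000, 9_000],
                 "end": [4_400, 9_400], "value": [10.0, 40.0]}
            )
        )
        track_p = TagTrack(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [4_000, 9_000],
                 "end": [4_400, 9_400], "value": [40.0, 10.0]}
            )
        )
        union = build_peak_union(minus, PeakSet([], "plus"))
        table = differential_table(union, track_m, track_p)
        mats = ranked_density_matrix(table, {"minus": track_m, "plus": track_p})
        gained_name = table.loc[table["fold"].idxmax(), "peak"]
        for mat in mats.values():
            assert mat.shape == (2, 200)
            assert mat.index[0] == gained_name
        assert mats["minus"].index.equals(mats["plus"].index)

    def test_constant_track_fills_every_cell_equally(self):
        minus = make_peaks([("chr1", 10_000, 10_400, 10_200, "m0")], "minus")
        union = build_peak_union(minus, PeakSet([], "plus"))
        table = differential_table(union, constant_track(2.0), constant_track(2.0))
        mat = ranked_density_matrix(table, {"t": constant_track(5.0)})["t"]
        assert np.allclose(mat.to_numpy(), 5.0)


class TestCorrelationCluster:
    def test_duplicated_and_negated_samples(self):
        base = np.arange(10, dtype=float)
        mat = pd.DataFrame([base, base, -base], index=["a", "b", "c"])
        corr, order = correlation_cluster(mat)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_identical_samples_are_sibling_leaves(self):
        rng = np.random.default_rng(4)
        v1 = rng.normal(size=20)
        v2 = rng.normal(size=20)
        mat = pd.DataFrame([v1, v2, v1], index=["x", "y", "x2"])
        _, order = correlation_cluster(mat)
        assert abs(order.index("x") - order.index("x2")) == 1

    def test_zero_variance_sample_named_in_error(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            correlation_cluster(mat)
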