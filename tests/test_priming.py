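"""Signature derivation and the resampling enrichment test.

The independent oracle throughout is the hypergeometric law: uniform
draws of n peaks without replacement from a universe of N peaks, K of
which overlap the signature, make the overlap count hypergeometric(N, K, n).
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from chromprime.intervals import GenomicInterval, Peak, PeakSet
from chromprime.priming import (
    derive_signatures,
    priming_panel,
    priming_test,
    subseed,
)

from conftest import make_peaks


def labelled_universe(n, hit_indices, start=0):
    """Universe of disjoint unit peaks; signature = peaks at hit_indices."""
    rows = [("chr1", start + 10 * i, start + 10 * i + 5, start + 10 * i + 2, f"u{i}")
            for i in range(n)]
    universe = make_peaks(rows, "universe")
    signature = make_peaks(
        [rows[i][:4] + (f"s{i}",) for i in hit_indices], "signature"
    )
    return universe, signature


class TestDeriveSignatures:
    def test_replicated_exclusive_peak_enters_signature(self):
        a_peak = [("chr1", 100, 200, 150)]
        b_peak = [("chr1", 1000, 1100, 1050)]
        atlas = derive_signatures(
            {
                "A": [make_peaks(a_peak, "a1"), make_peaks(a_peak, "a2")],
                "B": [make_peaks(b_peak, "b1"), make_peaks(b_peak, "b2")],
            }
        )
        assert len(atlas["A"]) == 1 and len(atlas["B"]) == 1

    def test_peak_in_two_cell_types_excluded_from_both(self):
        shared = [("chr1", 100, 200, 150)]
        atlas = derive_signatures(
            {
                "A": [make_peaks(shared, "a1"), make_peaks(shared, "a2")],
                "B": [make_peaks(shared, "b1"), make_peaks(shared, "b2")],
            }
        )
        assert len(atlas["A"]) == 0 and len(atlas["B"]) == 0

    def test_peak_in_single_replicate_excluded(self):
        atlas = derive_signatures(
            {
                "A": [
                    make_peaks([("chr1", 100, 200, 150), ("chr1", 500, 600, 550)], "a1"),
                    make_peaks([("chr1", 100, 200, 150)], "a2"),
                ],
                "B": [make_peaks([("chr1", 9000, 9100, 9050)], "b1")],
            }
        )
        assert len(atlas["A"]) == 1  # only the reproducible peak survives

    def test_single_cell_type_rejected(self):
        with pytest.raises(ValueError):
            derive_signatures({"A": [make_peaks([("chr1", 0, 10, 5)], "a")]})


class TestPrimingTest:
    def test_moments_match_hypergeometric_oracle(self):
        N, K, n = 20, 5, 8
        universe, signature = labelled_universe(N, range(K))
        test = universe.subset([i < n for i in range(N)], "test")
        res = priming_test(test, universe, signature, n_resamples=20_000, seed=5)
        rv = hypergeom(N, K, n)
        se_mu = rv.std() / np.sqrt(res.n_resamples)
        assert res.mu == pytest.approx(rv.mean(), abs=3 * se_mu)
        assert res.sigma == pytest.approx(rv.std(), rel=0.05)
        assert res.x == 5  # first n peaks include all K signature peaks

    def test_observed_count_and_exact_tail(self):
        N, K, n = 20, 5, 8
        universe, signature = labelled_universe(N, range(K))
        # test set holds 4 signature peaks and 4 background peaks: x = 4
        test = universe.subset(
            [i in (0, 1, 2, 3, 10, 11, 12, 13) for i in range(N)], "test"
        )
        res = priming_test(test, universe, signature, n_resamples=20_000, seed=5)
        assert res.x == 4
        exact = hypergeom(N, K, n).sf(4)
        se = np.sqrt(exact * (1 - exact) / res.n_resamples)
        assert res.p_enrich == pytest.approx(exact, abs=3.5 * se)

    def test_identical_seed_bit_identical_result(self):
        universe, signature = labelled_universe(50, range(10))
        test = universe.subset([i < 12 for i in range(50)], "test")
        r1 = priming_test(test, universe, signature, n_resamples=500, seed=42)
        r2 = priming_test(test, universe, signature, n_resamples=500, seed=42)
        assert r1 == r2

    def test_signature_covering_universe_degenerate(self):
        universe, signature = labelled_universe(10, range(10))
        test = universe.subset([i < 4 for i in range(10)], "test")
        res = priming_test(test, universe, signature, n_resamples=200, seed=1)
        assert res.degenerate and res.z is None and res.x == 4

    def test_disjoint_signature_degenerate_zero(self):
        universe, _ = labelled_universe(10, [])
        signature = make_peaks([("chr9", 0, 5, 2)], "sig")
        test = universe.subset([i < 4 for i in range(10)], "test")
        res = priming_test(test, universe, signature, n_resamples=200, seed=1)
        assert res.degenerate and res.x == 0 and res.mu == 0.0

    def test_test_set_outside_universe_rejected(self):
        universe, signature = labelled_universe(10, range(2))
        rogue = make_peaks([("chr7", 0, 5, 2, "rogue")], "rogue")
        with pytest.raises(ValueError):
            priming_test(rogue, universe, signature, n_resamples=10, seed=0)

    def test_smoothed_p_values_positive(self):
        universe, signature = labelled_universe(20, range(20))
        test = universe.subset([i < 5 for i in range(20)], "test")
        res = priming_test(test, universe, signature, n_resamples=99, seed=0,
                           smoothed=True)
        assert 0 < res.p_enrich <= 1 and 0 < res.p_deplete <= 1

    def test_z_and_p_monotone_in_observed_count(self):
        """Exact-oracle monotonicity: larger x, same null, never lowers z
        or raises the enrichment tail."""
        N, K, n = 30, 8, 10
        rv = hypergeom(N, K, n)
        mu, sd = rv.mean(), rv.std()
        zs = [(x - mu) / sd for x in range(n + 1)]
        tails = [rv.sf(x) for x in range(n + 1)]
        assert all(b > a for a, b in zip(zs, zs[1:]))
        assert all(b <= a for a, b in zip(tails, tails[1:]))


class TestSubseedsAndPanel:
    def test_subseed_stable_and_in_range(self):
        s = subseed(17, "cond", "gained", "megakaryocyte")
        assert s == subseed(17, "cond", "gained", "megakaryocyte")
        assert 0 <= s < 2**31
        assert s != subseed(17, "cond", "lost", "megakaryocyte")

    def test_panel_rows_and_determinism(self):
        table = pd.DataFrame(
            {
                "peak": [f"u{i}" for i in range(30)],
                "chrom": "chr1",
                "start": [10 * i for i in range(30)],
                "end": [10 * i + 5 for i in range(30)],
                "summit": [10 * i + 2 for i in range(30)],
                "element": "distal",
                "class": ["gained"] * 8 + ["lost"] * 8 + ["shared"] * 14,
            }
        )
        sig = make_peaks([("chr1", 10 * i, 10 * i + 5, 10 * i + 2) for i in range(5)], "s")
        from chromprime.priming import SignatureAtlas

        atlas = SignatureAtlas(signatures={"mk": sig, "ery": make_peaks([("chr2", 0, 5, 2)], "e")})
        p1 = priming_panel(table, atlas, n_resamples=300, seed=9)
        p2 = priming_panel(table, atlas, n_resamples=300, seed=9)
        pd.testing.assert_frame_equal(p1, p2)
        assert set(zip(p1["class"], p1["cell_type"])) == {
            ("gained", "mk"), ("gained", "ery"), ("lost", "mk"), ("lost", "ery")
        }

    def test_empty_class_flagged_absent(self):
        table = pd.DataFrame(
            {
                "peak": ["u0", "u1"], "chrom": "chr1",
                "start": [0, 10], "end": [5, 15], "summit": [2, 12],
                "element": "distal", "class": ["shared", "shared"],
            }
        )
        from chromprime.priming import SignatureAtlas

        atlas = SignatureAtlas(signatures={"mk": make_peaks([("chr1", 0, 5, 2)], "s")})
        panel = priming_panel(table, atlas, n_resamples=50, seed=0)
        assert panel["absent"].all()
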