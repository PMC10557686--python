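"""Fiber classification, haplotype counting, Fisher/BH behavior, and the
volcano-style per-peak testing."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fiberhap as fh
from fiberhap.haplotype_tests import ACCESSIBLE, INACCESSIBLE, NOT_SPANNING

from conftest import make_fiber, make_peak


def hypergeom_two_sided(a, b, c, d):
    """Minimum-likelihood two-sided Fisher p by exhaustive enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def point(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    obs = point(a)
    return sum(p for x in range(min(r1, c1) + 1) if (p := point(x)) <= obs * (1 + 1e-9))


class TestClassify:
    def test_not_spanning(self):
        f = make_fiber(0, 18_000)
        assert fh.classify_fiber_at_peak(f, make_peak(20_000, 20_200), 0.9) == NOT_SPANNING

    def test_accessible_and_inaccessible(self):
        peak = make_peak(5_000, 5_200)
        acc = make_fiber(0, 18_000, [(5_100, 5_300, 0.97)])
        low = make_fiber(0, 18_000, [(5_100, 5_300, 0.5)])
        off = make_fiber(0, 18_000, [(9_000, 9_200, 0.97)])
        assert fh.classify_fiber_at_peak(acc, peak, 0.90) == ACCESSIBLE
        assert fh.classify_fiber_at_peak(low, peak, 0.90) == INACCESSIBLE
        assert fh.classify_fiber_at_peak(off, peak, 0.90) == INACCESSIBLE

    def test_one_bp_overlap_counts(self):
        peak = make_peak(5_000, 5_200)
        f = make_fiber(0, 18_000, [(4_000, 5_001, 0.97)])
        assert fh.classify_fiber_at_peak(f, peak, 0.90) == ACCESSIBLE


class TestCounts:
    def test_no_spanning_fibers_zero_totals(self):
        (c,) = fh.peak_haplotype_counts([make_fiber(0, 100)], [make_peak(5_000, 5_100)], 0.9)
        assert (c.total_h1, c.total_h2) == (0, 0)

    def test_direct_count(self):
        peak = make_peak(5_000, 5_200)
        fibers = [
            make_fiber(0, 18_000, [(5_050, 5_150, 0.97)], fid=f"a{i}") for i in range(3)
        ] + [make_fiber(0, 18_000, [], fid="a3")]
        fibers += [make_fiber(0, 18_000, [], hap="H2", fid="b0")]
        fibers += [make_fiber(0, 18_000, [(5_050, 5_150, 0.97)], hap="UNASSIGNED", fid="u")]
        (c,) = fh.peak_haplotype_counts(fibers, [peak], 0.9)
        assert (c.acc_h1, c.total_h1, c.acc_h2, c.total_h2) == (3, 4, 0, 1)

    def test_duplicate_peak_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fh.peak_haplotype_counts([], [make_peak(0, 10, "p"), make_peak(20, 30, "p")], 0.9)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        fibers, peaks = [], []
        for i in range(200):
            s = int(rng.integers(0, 50_000))
            e = s + int(rng.integers(2_000, 20_000))
            msps, pos = [], s
            for _ in range(int(rng.integers(0, 5))):
                ms = pos + int(rng.integers(0, 3_000))
                me = ms + int(rng.integers(50, 300))
                if me > e:
                    break
                msps.append((ms, me, float(rng.random())))
                pos = me
            hap = ["H1", "H2", "UNASSIGNED"][int(rng.integers(3))]
            fibers.append(make_fiber(s, e, msps, hap=hap, fid=f"f{i}"))
        for j in range(30):
            s = int(rng.integers(0, 60_000))
            peaks.append(make_peak(s, s + int(rng.integers(100, 500)), pid=f"p{j}"))
        got = fh.peak_haplotype_counts(fibers, peaks, 0.9)
        for c, p in zip(got, peaks):
            acc = {"H1": 0, "H2": 0}
            tot = {"H1": 0, "H2": 0}
            for f in fibers:
                if f.haplotype == "UNASSIGNED":
                    continue
                state = fh.classify_fiber_at_peak(f, p, 0.9)
                if state == NOT_SPANNING:
                    continue
                tot[f.haplotype] += 1
                acc[f.haplotype] += state == ACCESSIBLE
            assert (c.acc_h1, c.total_h1, c.acc_h2, c.total_h2) == (
                acc["H1"], tot["H1"], acc["H2"], tot["H2"],
            )


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fh.fisher_exact_2x2(2, 2, 2, 2)[0] == pytest.approx(1.0)

    def test_fully_separated_table(self):
        # p = 2 / C(10,5) = 2/252
        p, odds = fh.fisher_exact_2x2(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert math.isinf(odds)

    def test_degenerate_column_p_one(self):
        p, odds = fh.fisher_exact_2x2(10, 0, 10, 0)
        assert p == pytest.approx(1.0)
        assert math.isnan(odds)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fh.fisher_exact_2x2(-1, 0, 0, 0)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            p, _ = fh.fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(hypergeom_two_sided(a, b, c, d), rel=1e-7, abs=1e-12)


class TestBH:
    def test_single_value_identity(self):
        assert fh.bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(fh.bh_fdr([0.2] * 5), 0.2)

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(fh.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fh.bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_bruteforce_stepup(self, ps):
        def brute(ps):
            m = len(ps)
            order = sorted(range(m), key=lambda i: ps[i])
            q = [0.0] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                q[i] = running
            return q

        np.testing.assert_allclose(fh.bh_fdr(ps), brute(ps), rtol=1e-12)


class TestVolcano:
    def test_balanced_counts_p_one(self):
        (r,) = fh.haplotype_specific_accessibility(
            [fh.HaplotypeCounts("p", 50, 100, 50, 100)]
        )
        assert r.abs_delta == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert not r.nominal_sig

    def test_strong_imbalance_detected(self):
        (r,) = fh.haplotype_specific_accessibility(
            [fh.HaplotypeCounts("p", 90, 100, 5, 100)]
        )
        assert r.abs_delta == pytest.approx(85.0)
        assert r.p_value < 1e-10
        assert r.nominal_sig and r.fdr_sig

    def test_empty_input_and_zero_margin_drop(self):
        assert fh.haplotype_specific_accessibility([]) == []
        out = fh.haplotype_specific_accessibility(
            [fh.HaplotypeCounts("p", 0, 0, 5, 10), fh.HaplotypeCounts("q", 3, 10, 5, 10)]
        )
        assert [r.peak_id for r in out] == ["q"]

    def test_q_values_are_bh_of_p_values(self):
        counts = [
            fh.HaplotypeCounts(f"p{i}", int(a), 40, int(b), 40)
            for i, (a, b) in enumerate(product(range(0, 40, 7), range(0, 40, 7)))
        ]
        res = fh.haplotype_specific_accessibility(counts)
        np.testing.assert_allclose(
            [r.q_value for r in res], fh.bh_fdr([r.p_value for r in res])
        )

    def test_invariant_counts_bound_percentages(self):
        with pytest.raises(ValueError):
            fh.HaplotypeCounts("p", 5, 4, 0, 0)
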