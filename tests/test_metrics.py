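"""Morphometrics, Levan classes, karyotype formula and asymmetry indices.

Oracle style: every index is re-derived in-line from raw per-pair arm
lengths with one-line brute-force formulas, independent of the library
code path.
"""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import karyostat as ks
from karyostat.metrics import asymmetry_suite, summarize_pairs

from conftest import random_karyotype, records_from_arms

arm_lists = st.lists(
    st.tuples(st.floats(0.3, 5.0), st.floats(1.0, 8.0)),
    min_size=2, max_size=12,
)


class TestSummarizePairs:
    def test_metacentric_identity(self):
        pairs = summarize_pairs(records_from_arms([1.0], [1.0]))
        assert pairs[0].AR == pytest.approx(1.0)
        assert pairs[0].CI == pytest.approx(50.0)
        assert pairs[0].levan_class == "M"

    def test_direct_arithmetic(self):
        pairs = summarize_pairs(records_from_arms([1.0], [3.0]))
        assert pairs[0].AR == pytest.approx(3.0)
        assert pairs[0].CI == pytest.approx(25.0)
        assert pairs[0].levan_class == "sm"  # AR = 3.00 is still sm

    def test_cell_level_doubling_leaves_rl_ar_ci(self):
        b, B = [1.0, 2.0, 0.7], [1.5, 2.5, 2.8]
        recs = records_from_arms(b, B, "c1") + records_from_arms(
            [2 * x for x in b], [2 * x for x in B], "c2")
        one = summarize_pairs(records_from_arms(b, B))
        two = summarize_pairs(recs)
        for p, q in zip(one, two):
            assert q.RL == pytest.approx(p.RL)
            assert q.AR == pytest.approx(p.AR)
            assert q.CI == pytest.approx(p.CI)

    def test_pairs_sorted_decreasing_rl_and_renumbered(self):
        pairs = summarize_pairs(records_from_arms([0.5, 2.0, 1.0],
                                                  [0.7, 2.5, 1.2]))
        assert [p.pair_id for p in pairs] == [1, 2, 3]
        assert [p.orig_pair_id for p in pairs] == [2, 3, 1]
        assert all(a.RL >= b.RL for a, b in zip(pairs, pairs[1:]))

    def test_rl_sums_to_100(self):
        rng = np.random.default_rng(7)
        b, B = random_karyotype(rng)
        pairs = summarize_pairs(records_from_arms(b, B))
        assert sum(p.RL for p in pairs) == pytest.approx(100.0, abs=1e-6)

    def test_empty_input_is_missing_pair_error(self):
        with pytest.raises(ks.MissingPairError):
            summarize_pairs([])


class TestLevan:
    @pytest.mark.parametrize("ar,expected", [
        (1.0, "M"), (1.5, "m"), (1.70, "m"), (1.7000001, "sm"),
        (2.5, "sm"), (3.0, "sm"), (3.0000001, "st"), (5.0, "st"),
        (7.0, "st"), (7.0000001, "t"), (12.0, "t"),
    ])
    def test_interval_table(self, ar, expected):
        assert ks.classify_levan(ar) == expected

    def test_ar_below_one_is_domain_error(self):
        with pytest.raises(ks.ValidationError):
            ks.classify_levan(0.9)


class TestKaryotypeFormula:
    def _pair(self, i, cls, sat=False):
        return ks.PairSummary(pair_id=i, orig_pair_id=i, b=1.0, B=1.0, AR=1.0,
                              CI=50.0, RL=100.0 / 11, levan_class=cls,
                              has_satellite=sat)

    def test_all_metacentric(self):
        assert ks.karyotype_formula([self._pair(i, "m") for i in range(1, 12)]) == "11m"

    def test_m_plus_sm(self):
        pairs = [self._pair(i, "m") for i in range(1, 10)] + \
                [self._pair(i, "sm") for i in (10, 11)]
        assert ks.karyotype_formula(pairs) == "9m + 2sm"

    def test_satellite_annotation(self):
        pairs = [self._pair(1, "m", sat=True)] + \
                [self._pair(i, "m") for i in range(2, 11)] + [self._pair(11, "sm")]
        assert ks.karyotype_formula(pairs) == "10m (1SAT) + 1sm"

    def test_median_class_merged_into_m(self):
        pairs = [self._pair(1, "M"), self._pair(2, "m"), self._pair(3, "st")]
        assert ks.karyotype_formula(pairs) == "2m + 1st"


class TestKaryotypeLength:
    def test_tcl_se_and_c_over_cells(self):
        b, B = [1.0, 2.0], [1.5, 2.5]
        recs = []
        for i, scale in enumerate((0.9, 1.0, 1.1), start=1):
            recs += records_from_arms([scale * x for x in b],
                                      [scale * x for x in B], f"c{i}")
        tcl, se, c = ks.karyotype_length(recs)
        totals = np.array([0.9, 1.0, 1.1]) * 7.0
        assert tcl == pytest.approx(totals.mean())
        assert se == pytest.approx(totals.std(ddof=1) / np.sqrt(3))
        assert c == pytest.approx(tcl / 2)

    def test_single_cell_se_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single metaphase"):
            tcl, se, c = ks.karyotype_length(records_from_arms([1.0], [2.0]))
        assert se == 0.0
        assert tcl == pytest.approx(3.0)


class TestAsymmetrySuite:
    def test_uniform_metacentric_symmetry_limit(self):
        pairs = summarize_pairs(records_from_arms([1.0, 1.0], [1.0, 1.0]))
        a = asymmetry_suite(pairs)
        assert a.a1 == pytest.approx(0.0)
        assert a.a2 == pytest.approx(0.0)
        assert a.ask_percent == pytest.approx(50.0)
        assert a.ai == pytest.approx(0.0)

    def test_a1_direct_sum(self):
        # two pairs with b/B = 0.5 and 1.0 -> A1 = 1 - (0.5+1)/2 = 0.25
        pairs = summarize_pairs(records_from_arms([1.0, 1.0], [2.0, 1.0]))
        assert asymmetry_suite(pairs).a1 == pytest.approx(0.25)

    def test_brute_force_oracle_equivalence(self):
        """Each index equals its one-line recomputation from raw arms."""
        rng = np.random.default_rng(20260930)
        for _ in range(1000):
            b, B = random_karyotype(rng)
            a = asymmetry_suite(summarize_pairs(records_from_arms(b, B)))
            L = b + B
            ci = 100 * b / L
            assert a.a1 == pytest.approx(1 - np.mean(b / B), abs=1e-9)
            assert a.a2 == pytest.approx(np.std(L, ddof=1) / np.mean(L), abs=1e-9)
            assert a.ask_percent == pytest.approx(100 * B.sum() / L.sum(), abs=1e-9)
            assert a.ci_mean == pytest.approx(ci.mean(), abs=1e-9)
            assert a.ci_sd == pytest.approx(np.std(ci, ddof=1), abs=1e-9)
            assert a.ai == pytest.approx(
                (100 * np.std(L, ddof=1) / np.mean(L))
                * (100 * np.std(ci, ddof=1) / ci.mean()) / 100, abs=1e-9)

    def test_single_pair_dispersion_undefined(self):
        with pytest.raises(ks.ValidationError):
            asymmetry_suite(summarize_pairs(records_from_arms([1.0], [2.0])))

    def test_ai_from_table_stats_reconstruction(self):
        assert round(ks.ai_from_table_stats(0.19, 43.24, 3.45), 2) == 1.52
        assert round(ks.ai_from_table_stats(0.20, 44.37, 3.13), 2) == 1.41

    @given(arm_lists)
    def test_ask_plus_weighted_ci_is_100(self, arms):
        b = [min(s, l) for s, l in arms]
        B = [max(s, l) for s, l in arms]
        pairs = summarize_pairs(records_from_arms(b, B))
        a = asymmetry_suite(pairs)
        w_ci = sum(p.L * p.CI for p in pairs) / sum(p.L for p in pairs)
        assert a.ask_percent + w_ci == pytest.approx(100.0, abs=1e-6)

    @given(arm_lists, st.floats(0.1, 10.0))
    def test_scale_invariance(self, arms, scale):
        b = [min(s, l) for s, l in arms]
        B = [max(s, l) for s, l in arms]
        p1 = summarize_pairs(records_from_arms(b, B))
        p2 = summarize_pairs(records_from_arms([scale * x for x in b],
                                               [scale * x for x in B]))
        a1, a2 = asymmetry_suite(p1), asymmetry_suite(p2)
        for f in ("a1", "a2", "ask_percent", "ci_mean", "ai"):
            assert getattr(a2, f) == pytest.approx(getattr(a1, f), rel=1e-9, abs=1e-9)
        for q1, q2 in zip(p1, p2):
            assert q2.RL == pytest.approx(q1.RL)
            assert q2.AR == pytest.approx(q1.AR)
            assert q2.CI == pytest.approx(q1.CI)
        t1, _, c1 = ks.karyotype_length(records_from_arms(b, B))
        t2, _, c2 = ks.karyotype_length(records_from_arms(
            [scale * x for x in b], [scale * x for x in B]))
        assert t2 == pytest.approx(scale * t1, rel=1e-9)
        assert c2 == pytest.approx(scale * c1, rel=1e-9)


class TestStebbins:
    def _pairs(self, ars, rls):
        return [ks.PairSummary(pair_id=i, orig_pair_id=i, b=1.0, B=ar, AR=ar,
                               CI=100 / (1 + ar), RL=rl,
                               levan_class=ks.classify_levan(ar))
                for i, (ar, rl) in enumerate(zip(ars, rls), start=1)]

    DIGITS = {"1": [1.5] * 4, "2": [2.5, 1.5, 1.5, 1.5],
              "3": [2.5, 2.5, 2.5, 1.5], "4": [2.5] * 4}
    LETTERS = {"A": [30.0, 26.0, 24.0, 20.0], "B": [40.0, 25.0, 20.0, 15.0],
               "C": [50.0, 25.0, 15.0, 10.0]}

    @pytest.mark.parametrize("digit", sorted(DIGITS))
    @pytest.mark.parametrize("letter", sorted(LETTERS))
    def test_full_truth_table(self, digit, letter):
        """All 12 (digit, letter) cells reachable and correct."""
        pairs = self._pairs(self.DIGITS[digit], self.LETTERS[letter])
        assert ks.stebbins_category(pairs) == digit + letter

    def test_ar_exactly_two_counts_as_symmetric(self):
        pairs = self._pairs([2.0] * 4, self.LETTERS["A"])
        assert ks.stebbins_category(pairs)[0] == "1"

    def test_identical_metacentric_complement(self):
        pairs = summarize_pairs(records_from_arms([1.0, 1.0], [1.0, 1.0]))
        assert ks.stebbins_category(pairs) == "1A"
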