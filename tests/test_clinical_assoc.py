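"""Contingency, rank-sum, correlation, histo-score, and survival statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recurdrift.clinical_assoc import (
    AssociationResult,
    ClinicalInputError,
    ClinicalRecord,
    HistologyRecord,
    bh_adjust,
    chi_square_rxc,
    fisher_exact_2x2,
    group_association_family,
    histoscore,
    logrank,
    median_split,
    spearman,
    table1_tests,
    wilcoxon_rank_sum,
)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    # printed cohort-description tables: receptor status, proliferation
    # marker, amplification, and age between primary and recurrent tumors
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[18, 16], [9, 8]], 1.000),  # ER positive/negative
            ([[11, 13], [15, 11]], 0.572),  # PgR
            ([[10, 8], [13, 16]], 0.556),  # Ki-67 low/high
            ([[18, 16], [4, 4]], 1.000),  # ERBB2 normal/amplified
            ([[13, 16], [14, 11]], 0.586),  # age >55 / <=55
        ],
    )
    def test_cohort_description_p_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=5e-4)

    def test_perfect_separation(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    @settings(max_examples=150, derandomize=True)
    @given(
        a=st.integers(0, 10), b=st.integers(0, 10), c=st.integers(0, 10), d=st.integers(0, 10)
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        table = [[a, b], [c, d]]
        arr = np.asarray(table)
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            return
        assert fisher_exact_2x2(table) == pytest.approx(fisher_enumeration_oracle(table), rel=1e-7)


class TestChiSquare:
    def test_grade_table_p_value(self):
        # 2x3 grade table, primary (0, 14, 9) vs recurrence (1, 13, 7)
        stat, df, p = chi_square_rxc([[0, 14, 9], [1, 13, 7]])
        assert df == 2
        assert p == pytest.approx(0.549, abs=5e-4)

    def test_proportional_table_statistic_zero(self):
        stat, df, p = chi_square_rxc([[10, 20, 30], [1, 2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df2_closed_form_identity(self, rng):
        for _ in range(10):
            table = rng.integers(1, 40, size=(2, 3))
            stat, df, p = chi_square_rxc(table)
            assert df == 2
            assert p == pytest.approx(math.exp(-stat / 2), abs=1e-9)


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_rank_sum([1, 1, 1], [1, 1, 1]) == 1.0

    def test_most_extreme_small_sample(self):
        # fully separated 3-vs-3: 2 of C(6,3)=20 orderings as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_matches_brute_force_enumeration(self, rng):
        # exact null by enumerating all group assignments, n <= 8, no ties
        for na in (2, 3, 4):
            for trial in range(3):
                pooled = rng.permutation(rng.normal(size=8))[: na + 4]
                a, b = pooled[:na], pooled[na:]
                u_obs = sum(1 for x in a for y in b if x > y)
                n = len(pooled)
                count = 0
                total = 0
                for idx in itertools.combinations(range(n), na):
                    aa = pooled[list(idx)]
                    bb = np.delete(pooled, list(idx))
                    u = sum(1 for x in aa for y in bb if x > y)
                    m = len(aa) * len(bb)
                    if min(u, m - u) <= min(u_obs, m - u_obs):
                        count += 1
                    total += 1
                assert wilcoxon_rank_sum(a, b) == pytest.approx(count / total, rel=1e-9)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_adjusted_at_least_raw_and_permutation_invariant(self, rng):
        p = rng.uniform(size=12)
        adjusted = np.array(bh_adjust(p))
        assert (adjusted >= p - 1e-15).all()
        perm = rng.permutation(12)
        assert np.allclose(np.array(bh_adjust(p[perm])), adjusted[perm])


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_rank_arithmetic_example(self):
        # d^2 = (1, 1, 1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ClinicalInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestHistoscore:
    def _cohort(self):
        return [
            HistologyRecord("p1", 20, 5),
            HistologyRecord("p2", 30, 10),
            HistologyRecord("p3", 40, 15),
        ]

    def test_record_at_cohort_means_scores_zero(self):
        cohort = self._cohort()
        assert histoscore(HistologyRecord("x", 30, 10), cohort) == pytest.approx(0.0)

    def test_one_sd_above_both_markers_scores_two(self):
        cohort = self._cohort()
        ki = np.array([20, 30, 40])
        leu = np.array([5, 10, 15])
        rec = HistologyRecord("x", 30 + ki.std(ddof=1), 10 + leu.std(ddof=1))
        assert histoscore(rec, cohort) == pytest.approx(2.0)

    def test_opposite_deviations_cancel(self):
        # +1 sd on Ki-67, -1 sd on leukocytes
        cohort = self._cohort()
        ki_sd = np.array([20, 30, 40]).std(ddof=1)
        leu_sd = np.array([5, 10, 15]).std(ddof=1)
        rec = HistologyRecord("x", 30 + ki_sd, 10 - leu_sd)
        assert histoscore(rec, cohort) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_marker_named_in_error(self):
        cohort = [HistologyRecord("p1", 30, 5), HistologyRecord("p2", 30, 10)]
        with pytest.raises(ClinicalInputError, match="Ki-67"):
            histoscore(cohort[0], cohort)


class TestMedianSplit:
    def test_even_split(self):
        groups = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert groups == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_odd_median_element_goes_low(self):
        groups = median_split({"a": 1, "b": 2, "c": 3})
        assert groups["b"] == "low"

    def test_all_equal_degenerate_warns(self):
        with pytest.warns(UserWarning):
            groups = median_split({"a": 5, "b": 5})
        assert set(groups.values()) == {"low"}


class TestLogrank:
    def test_identical_experience_p_one(self):
        groups = ["a", "a", "b", "b"]
        times = [5, 8, 5, 8]
        events = [True, True, True, True]
        stat, p = logrank(groups, times, events)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        # group A events at 1, 2, 3; group B censored at 10 (x3)
        groups = ["A"] * 3 + ["B"] * 3
        times = [1, 2, 3, 10, 10, 10]
        events = [True, True, True, False, False, False]
        # observed-minus-expected tabulation over the three event times
        e = 3 / 6 + 2 / 5 + 1 / 4
        v = (3 / 6) * (3 / 6) + (2 / 5) * (3 / 5) + (1 / 4) * (3 / 4)
        expected_stat = (3 - e) ** 2 / v
        stat, p = logrank(groups, times, events)
        assert stat == pytest.approx(expected_stat, rel=1e-6)

    def test_group_relabeling_leaves_p_unchanged(self):
        times = [2, 4, 6, 8, 10, 12]
        events = [True, False, True, True, False, True]
        g1 = ["x", "x", "x", "y", "y", "y"]
        g2 = ["y", "y", "y", "x", "x", "x"]
        assert logrank(g1, times, events)[1] == pytest.approx(logrank(g2, times, events)[1])

    def test_no_events_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            stat, p = logrank(["a", "b"], [1, 2], [False, False])
        assert p == 1.0


class TestTable1Suite:
    def _records(self):
        """Reconstruct the printed cohort counts as per-sample records."""
        records = []
        counts = {
            "ER": {("PT", "positive"): 18, ("PT", "negative"): 9, ("IBTR", "positive"): 16, ("IBTR", "negative"): 8},
            "PgR": {("PT", "positive"): 11, ("PT", "negative"): 15, ("IBTR", "positive"): 13, ("IBTR", "negative"): 11},
            "Ki67": {("PT", "low"): 10, ("PT", "high"): 13, ("IBTR", "low"): 8, ("IBTR", "high"): 16},
            "ERBB2": {("PT", "normal"): 18, ("PT", "amplified"): 4, ("IBTR", "normal"): 16, ("IBTR", "amplified"): 4},
            "age": {("PT", ">55"): 13, ("PT", "<=55"): 14, ("IBTR", ">55"): 16, ("IBTR", "<=55"): 11},
            "grade": {("PT", "low"): 0, ("PT", "intermediate"): 14, ("PT", "high"): 9,
                      ("IBTR", "low"): 1, ("IBTR", "intermediate"): 13, ("IBTR", "high"): 7},
        }
        i = 0
        for var, table in counts.items():
            field = {"ER": "er", "PgR": "pgr", "Ki67": "ki67", "ERBB2": "erbb2", "age": "age_group", "grade": "grade"}[var]
            for (role, level), n in table.items():
                for _ in range(n):
                    records.append(ClinicalRecord(f"p{i}", role, **{field: level}))
                    i += 1
        return records

    def test_reproduces_printed_p_values_to_three_decimals(self):
        results = {r.variable: r for r in table1_tests(self._records())}
        assert results["ER"].raw_p == pytest.approx(1.000, abs=5e-4)
        assert results["PgR"].raw_p == pytest.approx(0.572, abs=5e-4)
        assert results["Ki67"].raw_p == pytest.approx(0.556, abs=5e-4)
        assert results["ERBB2"].raw_p == pytest.approx(1.000, abs=5e-4)
        assert results["age"].raw_p == pytest.approx(0.586, abs=5e-4)
        assert results["grade"].raw_p == pytest.approx(0.549, abs=5e-4)

    def test_n_reflects_records_used(self):
        results = {r.variable: r for r in table1_tests(self._records())}
        assert results["ER"].n == 51  # 27 + 24 with ER recorded
        assert results["grade"].n == 44


class TestGroupAssociationFamily:
    def test_bh_family_and_filtering(self, rng):
        import pandas as pd

        patients = [f"p{i}" for i in range(16)]
        groups = {p: ("A" if i < 8 else "B") for i, p in enumerate(patients)}
        values = pd.DataFrame(
            {
                "shifted": np.concatenate([rng.normal(0, 1, 8), rng.normal(4, 1, 8)]),
                "null1": rng.normal(size=16),
                "null2": rng.normal(size=16),
            },
            index=patients,
        )
        results = group_association_family(values, groups, family="sig")
        by_name = {r.variable: r for r in results}
        assert by_name["sig:shifted"].adjusted_p >= by_name["sig:shifted"].raw_p - 1e-15
        assert by_name["sig:shifted"].adjusted_p < 0.05
        assert all(r.n == 16 for r in results)
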