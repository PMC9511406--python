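import math
from statistics import fmean

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrassay._critical_values import (
    COCHRAN_1PCT,
    GRUBBS_1PCT,
    cochran_critical_value,
    grubbs_critical_value,
)
from rrassay.interlab_stats import (
    cochran_test,
    compute_precision_cell,
    grubbs_test,
    summarize_study,
)


def anova_oracle(groups):
    """Brute-force balanced one-way random-effects decomposition straight
    from the mean-square definitions; independent of the implementation."""
    p = len(groups)
    n = len(groups[0])
    means = [fmean(g) for g in groups]
    grand = fmean(means)
    msw = sum(sum((x - m) ** 2 for x in g) for g, m in zip(groups, means)) / (p * (n - 1))
    msb = n * sum((m - grand) ** 2 for m in means) / (p - 1)
    s_r2 = msw
    s_L2 = max(0.0, (msb - msw) / n)
    return s_r2, s_L2, s_r2 + s_L2


class TestPrecisionCell:
    def test_matches_anova_oracle_on_worked_example(self):
        groups = {"A": [1.0, 1.2, 1.1], "B": [1.4, 1.5, 1.6], "C": [0.9, 1.0, 1.1]}
        cell = compute_precision_cell(groups)
        s_r2, s_L2, s_R2 = anova_oracle(list(groups.values()))
        assert cell.s_r2 == pytest.approx(s_r2, abs=1e-10)
        assert cell.s_L2 == pytest.approx(s_L2, abs=1e-10)
        assert cell.s_R2 == pytest.approx(s_R2, abs=1e-10)
        assert cell.p == 3
        assert cell.grand_mean == pytest.approx(fmean([1.1, 1.5, 1.0]))

    def test_all_identical_values_give_zero_variances(self):
        cell = compute_precision_cell({"A": [2.0, 2.0], "B": [2.0, 2.0]})
        assert cell.s_r == cell.s_L == cell.s_R == 0.0

    def test_location_shift_moves_between_lab_only(self):
        base = compute_precision_cell({"A": [1.0, 1.2], "B": [1.1, 1.3]})
        shifted = compute_precision_cell({"A": [1.0, 1.2], "B": [6.1, 6.3]})
        assert shifted.s_r2 == pytest.approx(base.s_r2, abs=1e-12)
        assert shifted.s_L2 > base.s_L2
        assert shifted.s_L2 > 0

    def test_truncation_branch_sets_between_lab_to_zero_exactly(self):
        # lab means identical, plenty of within-lab spread
        cell = compute_precision_cell({"A": [0.0, 2.0], "B": [1.0, 1.0], "C": [-1.0, 3.0]})
        assert cell.s_L2 == 0.0
        assert cell.s_R == cell.s_r

    def test_reproducibility_dominates_components(self):
        cell = compute_precision_cell({"A": [1.0, 1.4], "B": [2.0, 2.1], "C": [0.5, 0.6]})
        assert cell.s_R2 >= cell.s_r2
        assert cell.s_R2 >= cell.s_L2

    def test_single_value_lab_excluded_from_repeatability(self):
        full = compute_precision_cell({"A": [1.0, 1.2], "B": [1.5, 1.7]})
        with_single = compute_precision_cell({"A": [1.0, 1.2], "B": [1.5, 1.7], "C": [9.0]})
        assert with_single.s_r2 == pytest.approx(full.s_r2)
        assert ("C", "single_value") in with_single.flags
        assert with_single.p == 3  # still contributes to lab means

    def test_unbalanced_df_weighting_and_harmonic_n(self):
        groups = {"A": [1.0, 1.2, 1.4], "B": [2.0, 2.4]}
        cell = compute_precision_cell(groups)
        sA2, sB2 = np.var([1.0, 1.2, 1.4], ddof=1), np.var([2.0, 2.4], ddof=1)
        s_r2 = (2 * sA2 + 1 * sB2) / 3
        n_bar = 2 / (1 / 3 + 1 / 2)
        s_d2 = np.var([1.2, 2.2], ddof=1)
        assert cell.s_r2 == pytest.approx(s_r2, abs=1e-12)
        assert cell.s_L2 == pytest.approx(max(0.0, s_d2 - s_r2 / n_bar), abs=1e-12)

    def test_fewer_than_two_labs_rejected(self):
        with pytest.raises(ValueError, match="2 lab"):
            compute_precision_cell({"A": [1.0, 1.1]})

    @given(
        p=st.integers(2, 6),
        n=st.integers(2, 4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_anova_oracle_on_random_balanced_designs(self, p, n, seed):
        rng = np.random.default_rng(seed)
        groups = rng.normal(rng.normal(0, 1, (p, 1)), 0.5, (p, n))
        cell = compute_precision_cell({f"L{i}": row.tolist() for i, row in enumerate(groups)})
        s_r2, s_L2, s_R2 = anova_oracle(groups.tolist())
        assert cell.s_r2 == pytest.approx(s_r2, abs=1e-10)
        assert cell.s_L2 == pytest.approx(s_L2, abs=1e-10)
        assert cell.s_R2 == pytest.approx(s_R2, abs=1e-10)


class TestCochran:
    def test_upper_bound_when_one_lab_holds_all_variance(self):
        c, flagged = cochran_test([0.5, 0.0, 0.0, 0.0], n=3)
        assert c == 1.0
        assert flagged == 0

    def test_lower_bound_with_equal_variances(self):
        c, flagged = cochran_test([0.2] * 7, n=3)
        assert c == pytest.approx(1 / 7)
        assert flagged is None

    def test_flag_decision_matches_table_lookup(self):
        crit = cochran_critical_value(7, 3)
        mild = [1.0] * 6 + [10.0]     # C = 10/16 = 0.625 < 0.664
        strong = [1.0] * 6 + [20.0]   # C = 20/26 = 0.769 > 0.664
        c1, f1 = cochran_test(mild, n=3)
        c2, f2 = cochran_test(strong, n=3)
        assert (f1 is not None) == (c1 > crit)
        assert (f2 is not None) == (c2 > crit)
        assert f1 is None and f2 == 6

    def test_out_of_table_range_is_an_error(self):
        with pytest.raises(ValueError, match="tabulated"):
            cochran_critical_value(50, 3)
        with pytest.raises(ValueError, match="tabulated"):
            cochran_critical_value(7, 9)


class TestGrubbs:
    def test_symmetric_three_lab_statistic_is_one(self):
        g, flagged = grubbs_test([1.0, 2.0, 3.0])
        assert g == pytest.approx(1.0)
        assert flagged is None  # critical value at p=3 is 1.1547

    def test_zero_spread_gives_undefined_statistic(self):
        g, flagged = grubbs_test([2.0] * 5)
        assert g is None and flagged is None

    def test_extreme_lab_flag_matches_table(self):
        means = [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 25.0]
        g, flagged = grubbs_test(means)
        assert g > grubbs_critical_value(7)
        assert flagged == 6

    def test_too_few_labs(self):
        with pytest.raises(ValueError, match="3"):
            grubbs_test([1.0, 2.0])


class TestCriticalValueTables:
    def test_cochran_table_matches_generating_construction(self):
        from scipy import stats
        for (p, n) in [(3, 3), (7, 3), (7, 2), (10, 4), (30, 6)]:
            v = n - 1
            x = stats.f.ppf(0.01 / p, (p - 1) * v, v)
            assert COCHRAN_1PCT[(p, n)] == pytest.approx(1.0 / (1.0 + (p - 1) * x), abs=5e-5)

    def test_grubbs_table_matches_generating_construction(self):
        from scipy import stats
        for p in [3, 7, 12, 25, 40]:
            t = stats.t.ppf(1 - 0.01 / (2 * p), p - 2)
            g = (p - 1) / math.sqrt(p) * math.sqrt(t**2 / (p - 2 + t**2))
            assert GRUBBS_1PCT[p] == pytest.approx(g, abs=5e-5)

    def test_published_reference_values(self):
        # spot checks against the published 1% tables
        assert COCHRAN_1PCT[(7, 3)] == pytest.approx(0.664, abs=5e-4)
        assert COCHRAN_1PCT[(3, 3)] == pytest.approx(0.942, abs=5e-4)
        assert GRUBBS_1PCT[7] == pytest.approx(2.139, abs=5e-4)
        assert GRUBBS_1PCT[3] == pytest.approx(1.155, abs=5e-4)


class TestStudySummary:
    def _cell(self, lab_values, sub="X", conc=1.0):
        return compute_precision_cell(lab_values, sub, conc, "ug/ml")

    def test_singleton(self):
        cell = self._cell({"A": [1.0, 1.2], "B": [1.3, 1.5]})
        s = summarize_study([cell])
        assert s.mean_inter_lab_sd == pytest.approx(cell.s_R)
        assert s.range_inter_lab_sd == (cell.s_R, cell.s_R)

    def test_two_cells_mean_and_range(self):
        a = self._cell({"A": [1.0, 1.2], "B": [1.3, 1.5]}, conc=1.0)
        b = self._cell({"A": [2.0, 2.1], "B": [5.0, 5.3]}, conc=10.0)
        s = summarize_study([a, b])
        assert s.mean_inter_lab_sd == pytest.approx((a.s_R + b.s_R) / 2)
        assert s.range_inter_lab_sd == (min(a.s_R, b.s_R), max(a.s_R, b.s_R))
        assert s.range_inter_lab_sd[0] <= s.mean_inter_lab_sd <= s.range_inter_lab_sd[1]
        intra = [sd for c in (a, b) for sd in c.intra_lab_sd.values()]
        assert s.mean_intra_lab_sd == pytest.approx(fmean(intra))
        assert s.heatmap_wide().shape == (1, 2)

    def test_between_lab_metric(self):
        a = self._cell({"A": [1.0, 1.2], "B": [1.3, 1.5]})
        s = summarize_study([a], metric="between_lab")
        assert s.mean_inter_lab_sd == pytest.approx(a.s_L)
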