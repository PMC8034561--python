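"""Stratified CMH test, minimum attainable p-value, prunability, grids."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import netsegmine as nm
from netsegmine.stats import Margins, StratifiedTable

from conftest import (
    cmh_pvalue_reference,
    is_prunable_box_enumeration,
    min_pvalue_exhaustive,
    random_margins,
)


class TestBuildTables:
    def test_counting_example(self):
        t = nm.build_tables([1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1])
        assert (t.a[0], t.x[0], t.n1[0], t.n[0]) == (1, 2, 2, 4)

    def test_perfect_association_is_diagonal(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        t = nm.build_tables(y, y, np.ones(6, dtype=int))
        assert t.a[0] == t.n1[0] == t.x[0] == 3

    def test_random_counts_match_bruteforce_loops(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            K = int(rng.integers(1, 4))
            w = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            c = rng.integers(1, K + 1, n)
            c[:K] = np.arange(1, K + 1)  # every class non-empty
            t = nm.build_tables(w, y, c)
            for k in range(1, K + 1):
                assert t.a[k - 1] == sum(
                    1 for j in range(n) if w[j] and y[j] and c[j] == k
                )
                assert t.x[k - 1] == sum(1 for j in range(n) if w[j] and c[j] == k)
                assert t.n1[k - 1] == sum(1 for j in range(n) if y[j] and c[j] == k)
                assert t.n[k - 1] == sum(1 for j in range(n) if c[j] == k)

    def test_infeasible_cell_counts_rejected(self):
        with pytest.raises(ValueError):
            StratifiedTable(a=[3], x=[2], n1=[5], n=[10])


class TestCmhPvalue:
    def test_null_expectation_gives_p_one(self):
        # a exactly equals x*n1/n: zero statistic
        t = StratifiedTable(a=[5], x=[10], n1=[10], n=[20])
        assert nm.cmh_pvalue(t) == 1.0

    def test_degenerate_support_gives_p_one(self):
        t = StratifiedTable(a=[0], x=[0], n1=[10], n=[20])
        assert nm.cmh_pvalue(t) == 1.0

    def test_reference_value_frozen(self):
        t = StratifiedTable(a=[8], x=[10], n1=[10], n=[20])
        assert nm.cmh_pvalue(t) == pytest.approx(0.008913883907440268, rel=1e-10)

    def test_matches_independent_loop_formula(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 4))
            x, n1, n = random_margins(rng, K)
            lo = np.maximum(0, x - (n - n1))
            hi = np.minimum(x, n1)
            a = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)])
            t = StratifiedTable(a=a, x=x, n1=n1, n=n)
            assert nm.cmh_pvalue(t) == pytest.approx(
                cmh_pvalue_reference(a, x, n1, n), rel=1e-9, abs=1e-12
            )

    def test_matches_statsmodels_stratified_table(self, rng):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        checked = 0
        for _ in range(100):
            K = int(rng.integers(1, 4))
            x, n1, n = random_margins(rng, K)
            if np.any(x == 0) or np.any(x == n) or np.any(n1 == 0) or np.any(n1 == n):
                continue
            lo = np.maximum(0, x - (n - n1))
            hi = np.minimum(x, n1)
            a = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)])
            tables = np.array([
                [[ai, n1i - ai], [xi - ai, ni - n1i - xi + ai]]
                for ai, xi, n1i, ni in zip(a, x, n1, n)
            ]).T  # statsmodels wants 2 x 2 x K
            res = sm.StratifiedTable(tables.astype(float)).test_null_odds(
                correction=False
            )
            ours = nm.cmh_pvalue(StratifiedTable(a=a, x=x, n1=n1, n=n))
            assert ours == pytest.approx(res.pvalue, rel=1e-8, abs=1e-12)
            checked += 1
        assert checked > 20

    def test_single_stratum_is_scaled_pearson_chi2(self, rng):
        # with the (n - 1) variance convention the single-stratum statistic
        # equals Pearson's chi-squared times the exact factor (n - 1) / n
        from scipy.stats import chi2 as chi2_dist

        for _ in range(50):
            x, n1, n = random_margins(rng, 1)
            if x[0] in (0, n[0]) or n1[0] in (0, n[0]):
                continue
            lo = max(0, x[0] - (n[0] - n1[0]))
            hi = min(x[0], n1[0])
            a = int(rng.integers(lo, hi + 1))
            table = [[a, n1[0] - a], [x[0] - a, n[0] - n1[0] - x[0] + a]]
            pearson_t = chi2_contingency(table, correction=False).statistic
            expected = chi2_dist.sf(pearson_t * (n[0] - 1) / n[0], 1)
            ours = nm.cmh_pvalue(StratifiedTable(a=[a], x=x, n1=n1, n=n))
            if not np.isnan(expected):
                assert ours == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_invariant_under_within_class_permutation(self, rng):
        n, K = 40, 2
        w = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        c = np.resize(np.arange(1, K + 1), n)
        p0 = nm.cmh_pvalue(nm.build_tables(w, y, c))
        for _ in range(10):
            w2, y2 = w.copy(), y.copy()
            for k in range(1, K + 1):
                idx = np.flatnonzero(c == k)
                perm = rng.permutation(idx)
                w2[idx], y2[idx] = w2[perm], y2[perm]
            assert nm.cmh_pvalue(nm.build_tables(w2, y2, c)) == pytest.approx(p0)


class TestMinPvalue:
    def test_zero_support_gives_one(self):
        assert nm.min_pvalue(Margins(x=[0, 0], n1=[5, 5], n=[10, 10])) == 1.0

    def test_saturated_support_gives_one(self):
        assert nm.min_pvalue(Margins(x=[10, 10], n1=[5, 5], n=[10, 10])) == 1.0

    def test_two_class_example_frozen(self):
        m = Margins(x=[3, 2], n1=[5, 5], n=[10, 10])
        assert nm.min_pvalue(m) == pytest.approx(0.013663712868181249, rel=1e-10)

    def test_corner_evaluation_equals_exhaustive(self, rng):
        for _ in range(300):
            K = int(rng.integers(1, 4))
            x, n1, n = random_margins(rng, K, n_max=12)
            assert nm.min_pvalue(Margins(x, n1, n)) == pytest.approx(
                min_pvalue_exhaustive(x, n1, n), rel=1e-9, abs=1e-12
            )

    def test_lower_bounds_every_realisable_pvalue(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 3))
            x, n1, n = random_margins(rng, K, n_max=15)
            lo = np.maximum(0, x - (n - n1))
            hi = np.minimum(x, n1)
            a = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)])
            pmin = nm.min_pvalue(Margins(x, n1, n))
            p = nm.cmh_pvalue(StratifiedTable(a=a, x=x, n1=n1, n=n))
            assert pmin <= p + 1e-12


class TestIsPrunable:
    def test_saturated_margins_prunable(self):
        m = Margins(x=[10, 8], n1=[5, 4], n=[10, 8])
        assert nm.is_prunable(m, 0.5)

    def test_delta_one_never_prunable(self):
        m = Margins(x=[10, 8], n1=[5, 4], n=[10, 8])
        assert not nm.is_prunable(m, 1.0)

    def test_single_class_example_matches_box_enumeration(self):
        m = Margins(x=[16], n1=[10], n=[20])
        expected = is_prunable_box_enumeration([16], [10], [20], 1e-4)
        assert nm.is_prunable(m, 1e-4) == expected
        assert expected is True  # box minimum is 0.0293 > 1e-4

    @pytest.mark.parametrize("delta", [1e-6, 1e-3, 0.05, 0.5])
    def test_matches_box_enumeration_on_random_margins(self, rng, delta):
        for _ in range(40):
            K = int(rng.integers(1, 3))
            x, n1, n = random_margins(rng, K, n_max=8)
            assert nm.is_prunable(Margins(x, n1, n), delta) == \
                is_prunable_box_enumeration(x, n1, n, delta)


class TestThresholdGrid:
    def test_geometric_grid_contract(self):
        grid = nm.threshold_grid(floor=1e-12, ratio=0.5)
        assert grid[0] == 1.0
        assert len(grid) == 42  # 41 values after the leading 1
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] <= 1e-12

    def test_default_grid_reaches_floor(self):
        grid = nm.threshold_grid()
        assert grid[-1] <= 1e-30
        assert np.all(np.diff(grid) < 0)

    def test_exact_grid_enumerates_achievable_values(self):
        n, n1 = 18, 7
        grid = nm.exact_threshold_grid(n, n1)
        achievable = sorted(
            {nm.min_pvalue(Margins([x], [n1], [n])) for x in range(n + 1)},
            reverse=True,
        )
        if achievable[0] != 1.0:
            achievable = [1.0] + achievable
        assert np.allclose(grid, achievable)
        assert np.all(np.diff(grid) < 0)
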