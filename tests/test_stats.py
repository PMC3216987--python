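"""2x2 statistics: chi-square, Fisher, odds ratios, permutation adjustment, power.

Oracles: a brute-force hypergeometric enumeration for Fisher's exact test,
scipy's contingency routines as independent library cross-checks, exhaustive
label enumeration for the permutation adjustment, and the closed-form
two-proportion normal approximation for power.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from haplocase.stats import (
    ContingencyTable2x2,
    CohortDataset,
    choose_test,
    dataset_from_counts,
    fisher_two_tailed,
    nominal_p,
    odds_ratio_ci,
    pearson_chi2,
    permutation_adjust,
    pool,
    power_simulation,
    run_association_suite,
)


def fisher_enumeration_oracle(t: ContingencyTable2x2) -> float:
    """Exhaustive two-sided Fisher: enumerate all tables with the observed
    margins and sum the probabilities of those no more likely than observed."""
    a, b, c, d = t.cells
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(c1, r1)
    p_obs = table_prob(a)
    return sum(table_prob(x) for x in range(lo, hi + 1)
               if table_prob(x) <= p_obs * (1 + 1e-9))


small_cell = st.integers(0, 12)


class TestChi2:
    def test_published_d4_row_plain(self):
        _, p = pearson_chi2(ContingencyTable2x2(58, 246, 115, 728))
        assert round(p, 3) == 0.023

    def test_published_b4_row_needs_continuity(self):
        t = ContingencyTable2x2(126, 717, 196, 1493)
        assert round(pearson_chi2(t, continuity=True)[1], 3) == 0.021
        assert round(pearson_chi2(t, continuity=False)[1], 3) == 0.017

    def test_no_association_balanced_table(self):
        stat, p = pearson_chi2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0 and p == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            pearson_chi2(ContingencyTable2x2(0, 5, 0, 7))

    @given(a=st.integers(1, 60), b=st.integers(1, 60),
           c=st.integers(1, 60), d=st.integers(1, 60),
           continuity=st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_and_transposition(self, a, b, c, d, continuity):
        t = ContingencyTable2x2(a, b, c, d)
        stat, p = pearson_chi2(t, continuity)
        ref = sps.chi2_contingency([[a, b], [c, d]], correction=continuity)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert pearson_chi2(t.transposed(), continuity)[0] == pytest.approx(stat)


class TestFisher:
    def test_extreme_table(self):
        assert fisher_two_tailed(ContingencyTable2x2(0, 5, 5, 0)) == \
            pytest.approx(2 / 252)

    def test_symmetric_table_is_one(self):
        assert fisher_two_tailed(ContingencyTable2x2(2, 3, 3, 2)) == 1.0

    def test_exhaustive_small_tables_match_enumeration(self):
        """Every 2x2 table with n <= 18 agrees with the enumeration oracle."""
        for n in range(1, 19):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        t = ContingencyTable2x2(a, b, c, n - a - b - c)
                        assert fisher_two_tailed(t) == \
                            pytest.approx(fisher_enumeration_oracle(t), abs=1e-12), t

    @given(a=small_cell, b=small_cell, c=small_cell, d=small_cell)
    @settings(max_examples=80, deadline=None)
    def test_matches_oracle_and_scipy(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        p = fisher_two_tailed(t)
        assert p == pytest.approx(fisher_enumeration_oracle(t), abs=1e-12)
        assert p == pytest.approx(
            sps.fisher_exact([[a, b], [c, d]], "two-sided")[1], abs=1e-9)


class TestChooseTest:
    @pytest.mark.parametrize("cells,expected", [
        ((4, 300, 164, 679), "fisher"),
        ((42, 262, 119, 1570), "chi2"),
        ((0, 304, 17, 826), "fisher"),
        ((5, 5, 5, 5), "chi2"),
    ])
    def test_rule(self, cells, expected):
        assert choose_test(ContingencyTable2x2(*cells)) == expected


class TestOddsRatio:
    def test_published_f_row(self):
        or_, lo, hi, fb = odds_ratio_ci(ContingencyTable2x2(3, 301, 274, 1415))
        assert (round(or_, 3), round(lo, 3), round(hi, 3), fb) == \
            (0.051, 0.016, 0.162, False)

    def test_published_m7b_row(self):
        or_, lo, hi, _ = odds_ratio_ci(ContingencyTable2x2(42, 262, 119, 1570))
        assert (round(or_, 3), round(lo, 3), round(hi, 3)) == (2.115, 1.453, 3.078)

    def test_zero_cell_fallback_published_rows(self):
        # relative risk of control-group membership, log CI, flagged
        for cells, expect in [
            ((0, 304, 17, 826), (0.731, 0.706, 0.757)),
            ((0, 304, 7, 836), (0.733, 0.708, 0.759)),
            ((0, 304, 48, 1641), (0.844, 0.828, 0.860)),
            ((0, 304, 4, 1685), (0.847, 0.831, 0.863)),
        ]:
            v, lo, hi, fb = odds_ratio_ci(ContingencyTable2x2(*cells))
            assert fb and (round(v, 3), round(lo, 3), round(hi, 3)) == expect

    def test_double_zero_is_na(self):
        v, lo, hi, fb = odds_ratio_ci(ContingencyTable2x2(0, 5, 0, 7))
        assert fb and math.isnan(v) and math.isnan(lo) and math.isnan(hi)

    @given(a=st.integers(1, 200), b=st.integers(1, 200),
           c=st.integers(1, 200), d=st.integers(1, 200))
    @settings(max_examples=80, deadline=None)
    def test_reciprocal_symmetry_and_coverage(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        or_, lo, hi, _ = odds_ratio_ci(t)
        or_sw, lo_sw, hi_sw, _ = odds_ratio_ci(t.swapped_cohorts())
        assert or_sw == pytest.approx(1 / or_)
        assert lo_sw == pytest.approx(1 / hi) and hi_sw == pytest.approx(1 / lo)
        assert lo <= or_ <= hi


def two_class_dataset(name, rows):
    ids = [f"{name}{i}" for i in range(len(rows))]
    return CohortDataset(name, ids, ["X", "Y"], np.array(rows, dtype=bool))


class TestPermutation:
    def test_exhaustive_enumeration_small_dataset(self):
        """6 samples, 3+3 split: all C(6,3)=20 label assignments enumerated by
        hand give the exact adjusted p; Monte-Carlo at large B must agree."""
        # memberships: X carried by samples 0,1; Y carried by samples 0,2,4
        mem = np.array([[1, 1], [1, 0], [0, 1], [0, 0], [0, 1], [0, 0]], dtype=bool)
        case = CohortDataset("case", ["s0", "s1", "s2"], ["X", "Y"], mem[:3])
        ctrl = CohortDataset("ctrl", ["s3", "s4", "s5"], ["X", "Y"], mem[3:])

        # exact distribution of min-p over all 20 assignments
        def table_p(a, m):
            t = ContingencyTable2x2(a, 3 - a, m - a, 3 - (m - a))
            return nominal_p(t)[1]

        m = mem.sum(axis=0)
        p_obs = np.array([table_p(int(mem[:3, j].sum()), int(m[j]))
                          for j in range(2)])
        minps = []
        for case_idx in itertools.combinations(range(6), 3):
            sel = np.zeros(6, dtype=bool)
            sel[list(case_idx)] = True
            minps.append(min(table_p(int(mem[sel, j].sum()), int(m[j]))
                             for j in range(2)))
        exact = np.array([(np.sum(np.array(minps) <= p * (1 + 1e-12))) / 20
                          for p in p_obs])

        nom, adj, _ = permutation_adjust(case, ctrl, B=20000, seed=3)
        assert nom == pytest.approx(p_obs)
        # (r+1)/(B+1) estimator converges to the exact exceedance probability
        assert adj == pytest.approx(np.maximum(exact, p_obs), abs=0.02)

    def test_monotone_and_floor(self, tree):
        counts_case = {"F": 3, "M7b": 42, "D4": 58}
        counts_ctrl = {"F": 274, "M7b": 119, "D4": 252}
        classes = list(counts_case)
        case = dataset_from_counts("case", counts_case, 304, tree, classes)
        ctrl = dataset_from_counts("ctrl", counts_ctrl, 1689, tree, classes)
        nom, adj, floor = permutation_adjust(case, ctrl, B=2000, seed=9)
        assert (adj >= nom).all()
        j = classes.index("F")
        assert floor[j] and adj[j] == pytest.approx(max(1 / 2001, nom[j]))

    def test_single_class_adjusted_near_nominal(self, tree):
        classes = ["M7b"]
        case = dataset_from_counts("case", {"M7b": 42}, 304, tree, classes)
        ctrl = dataset_from_counts("ctrl", {"M7b": 119}, 1689, tree, classes)
        nom, adj, _ = permutation_adjust(case, ctrl, B=10000, seed=4)
        # single test: the permutation p of the test against itself; the
        # chi-square approximation error is the only gap
        assert adj[0] == pytest.approx(nom[0], abs=3 * math.sqrt(0.0001 / 10000) + 5e-4)

    def test_input_validation(self, tree):
        case = dataset_from_counts("case", {"F": 3}, 304, tree, ["F"])
        ctrl = dataset_from_counts("ctrl", {"F": 274}, 1689, tree, ["F"])
        with pytest.raises(ValueError, match="B"):
            permutation_adjust(case, ctrl, B=0)


class TestSuiteAndPool:
    def test_identical_cohorts_are_null(self, tree):
        classes = ["F", "M7b", "D4"]
        ds = dataset_from_counts("a", {"F": 30, "M7b": 20, "D4": 40}, 200, tree, classes)
        ds2 = dataset_from_counts("b", {"F": 30, "M7b": 20, "D4": 40}, 200, tree, classes)
        rows = run_association_suite(ds, ds2, B=200, seed=0)
        for r in rows:
            assert r.nominal_p == pytest.approx(1.0)
            assert r.or_value == pytest.approx(1.0)
            assert not r.significant

    def test_pool_additivity_and_errors(self, tree):
        classes = ["F", "M7b"]
        a = dataset_from_counts("new", {"F": 3, "M7b": 42}, 304, tree, classes)
        b = dataset_from_counts("old", {"F": 3, "M7b": 15}, 175, tree, classes)
        merged = pool(a, b)
        assert merged.n == 479
        assert merged.class_counts() == {"F": 6, "M7b": 57}
        empty = CohortDataset("e", [], classes, np.zeros((0, 2), dtype=bool))
        assert pool(a, empty).n == a.n
        with pytest.raises(ValueError, match="collision"):
            pool(a, a)

    def test_counts_reconstruction_respects_nesting(self, tree):
        classes = ["R9", "F", "F1", "F1a"]
        counts = {"R9": 305, "F": 274, "F1": 193, "F1a": 132}
        ds = dataset_from_counts("han", counts, 1689, tree, classes)
        assert ds.class_counts() == counts
        # F1a carriers are F1, F and R9 carriers too
        j = {c: i for i, c in enumerate(ds.classes)}
        rows_f1a = ds.membership[:, j["F1a"]]
        assert (ds.membership[rows_f1a][:, j["F1"]]).all()
        assert (ds.membership[rows_f1a][:, j["R9"]]).all()


class TestPower:
    def test_type_one_error_calibrated(self):
        rate = power_simulation(0.12, 0.12, 304, 843, reps=3000, seed=11)
        mc_se = math.sqrt(0.05 * 0.95 / 3000)
        assert abs(rate - 0.05) < 2 * mc_se + 0.01

    def test_monotone_in_sample_size(self):
        powers = [power_simulation(0.14, 0.07, n, 3 * n, reps=1500, seed=2)
                  for n in (100, 300, 1000)]
        assert powers[0] < powers[1] < powers[2]

    def test_against_normal_approximation(self):
        # OR = 2.1 at control frequency 0.07 -> case frequency
        p0 = 0.07
        odds = 2.1 * p0 / (1 - p0)
        p1 = odds / (1 + odds)
        n1, n0 = 304, 1689
        pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
        se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
        se1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
        z = sps.norm.ppf(0.975)
        closed = sps.norm.sf((z * se0 - (p1 - p0)) / se1) + \
            sps.norm.cdf((-z * se0 - (p1 - p0)) / se1)
        mc = power_simulation(p1, p0, n1, n0, reps=4000, seed=8)
        assert abs(mc - closed) < 0.03

    def test_validation(self):
        with pytest.raises(ValueError):
            power_simulation(1.2, 0.1, 10, 10)
        with pytest.raises(ValueError):
            power_simulation(0.1, 0.1, 10, 10, reps=10)
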