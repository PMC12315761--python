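"""Matching, abnormality flagging and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import comb

import chdcortex as cc


def make_cohort(case_ages, control_ages, case_sex=None, control_sex=None):
    n_case, n_ctl = len(case_ages), len(control_ages)
    return pd.DataFrame({
        "subject_id": [f"P{i}" for i in range(n_case)]
        + [f"C{i}" for i in range(n_ctl)],
        "group": [1] * n_case + [0] * n_ctl,
        "age": list(case_ages) + list(control_ages),
        "sex": (case_sex or [0] * n_case) + (control_sex or [0] * n_ctl),
    })


class TestMatching:
    def test_exact_duplicates_match_at_zero_distance(self):
        cohort = make_cohort([20, 25, 30], [30, 20, 25, 40])
        res = cc.match_controls(cohort)
        assert all(d == 0 for _, _, d in res.pairs)

    def test_greedy_nearest_neighbour_oracle(self):
        # cases 20, 30 vs controls 21, 29, 40: exhaustive check of the
        # in-order greedy rule gives (20-21), (30-29)
        cohort = make_cohort([20, 30], [21, 29, 40])
        res = cc.match_controls(cohort)
        assert [(p[0], p[1]) for p in res.pairs] == [("P0", "C0"), ("P1", "C1")]
        assert res.unmatched_controls == ["C2"]

    def test_fewer_controls_than_cases_raises(self):
        cohort = make_cohort([20, 25, 30], [22, 26])
        with pytest.raises(ValueError, match="controls"):
            cc.match_controls(cohort)

    def test_matching_is_idempotent(self):
        cohort = make_cohort([20, 25, 30, 35], [21, 27, 29, 36, 50, 12])
        first = cc.match_controls(cohort)
        matched = cohort[cohort.subject_id.isin(first.matched_ids)].reset_index(
            drop=True
        )
        second = cc.match_controls(matched)
        assert [(p[0], p[1]) for p in first.pairs] == [
            (p[0], p[1]) for p in second.pairs
        ]

    def test_sex_dominates_when_ages_tie(self):
        cohort = make_cohort([20], [20, 20], control_sex=[1, 0])
        res = cc.match_controls(cohort)
        assert res.pairs[0][1] == "C1"


class TestFlagAbnormal:
    def test_cutoff_is_inclusive(self):
        flags, _ = cc.flag_abnormal([65.0, 64.9, 70.0, 50.0])
        assert list(flags) == [1, 0, 1, 0]

    def test_proportion_matches_printed_convention(self):
        # 16 abnormal of 56 -> 28.6%
        scores = np.r_[np.full(16, 70.0), np.full(40, 50.0)]
        _, prop = cc.flag_abnormal(scores)
        assert round(100 * prop, 1) == 28.6

    def test_missing_excluded_from_denominator(self):
        flags, prop = cc.flag_abnormal([70.0, np.nan, 50.0])
        assert np.isnan(flags[1])
        assert prop == 0.5

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="all-missing"):
            cc.flag_abnormal([np.nan, np.nan])


def fisher_two_sided_enumeration(a, b, c, d):
    """Oracle: enumerate every 2x2 table with the observed margins and sum
    hypergeometric probabilities <= the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_p(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestProportions:
    @pytest.mark.parametrize("table,printed", [
        ((16, 40, 5, 51), 0.014),
        ((10, 46, 1, 55), 0.008),
        ((11, 45, 3, 53), 0.042),
        ((13, 43, 2, 54), 0.004),
    ])
    def test_fisher_reproduces_printed_pvalues(self, table, printed):
        res = cc.compare_proportions(*table, method="fisher")
        assert res.test_name == "fisher_exact"
        assert abs(res.p_value - printed) < 1e-3
        assert abs(res.p_value - fisher_two_sided_enumeration(*table)) < 1e-10

    def test_identical_proportions_give_p_one(self):
        res = cc.compare_proportions(5, 51, 5, 51, method="fisher")
        assert res.p_value == pytest.approx(1.0)

    def test_auto_gate_on_expected_counts(self):
        # min expected count 1.0 -> Fisher
        assert cc.compare_proportions(2, 8, 0, 10).test_name == "fisher_exact"
        # min expected count 10.5 -> chi-square without continuity correction
        res = cc.compare_proportions(16, 40, 5, 51)
        assert res.test_name == "chi_square"
        expected = stats.chi2_contingency([[16, 40], [5, 51]],
                                          correction=False).pvalue
        assert res.p_value == pytest.approx(expected)

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_transposing_groups_preserves_p(self, table):
        a, b, c, d = table
        forward = cc.compare_proportions(a, b, c, d)
        swapped = cc.compare_proportions(c, d, a, b)
        assert forward.p_value == pytest.approx(swapped.p_value, rel=1e-10)
        assert forward.test_name == swapped.test_name

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            cc.compare_proportions(-1, 5, 2, 3)


def ancova_f_oracle(y, X_full, X_red):
    """Normal-equations least squares, no shortcuts shared with the code."""
    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return r @ r

    df2 = len(y) - X_full.shape[1]
    F = (rss(X_red) - rss(X_full)) / (rss(X_full) / df2)
    return F, stats.f.sf(F, 1, df2)


class TestAncova:
    def setup_method(self):
        self.y = np.array([3.1, 4.0, 5.2, 4.8, 6.0, 5.5, 7.1, 6.6])
        self.g = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        self.cov = pd.DataFrame({
            "age": [20, 22, 25, 28, 21, 24, 26, 29],
            "sex": [0, 1, 0, 1, 0, 1, 0, 1],
        })

    def test_matches_normal_equations_oracle(self):
        res = cc.ancova_group_test(self.y, self.g, self.cov)
        X_red = np.column_stack([np.ones(8), self.cov.to_numpy(float)])
        X_full = np.column_stack([X_red, self.g])
        F, p = ancova_f_oracle(self.y, X_full, X_red)
        assert res.statistic == pytest.approx(F, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)
        assert res.df == (1, 4)

    def test_location_and_row_permutation_invariance(self):
        base = cc.ancova_group_test(self.y, self.g, self.cov).statistic
        shifted = cc.ancova_group_test(self.y + 100.0, self.g, self.cov).statistic
        assert shifted == pytest.approx(base, rel=1e-10)
        perm = np.array([3, 1, 4, 0, 7, 5, 2, 6])
        permuted = cc.ancova_group_test(
            self.y[perm], self.g[perm], self.cov.iloc[perm].reset_index(drop=True)
        ).statistic
        assert permuted == pytest.approx(base, rel=1e-10)

    def test_collinear_design_raises(self):
        cov = self.cov.copy()
        cov["age2"] = 2 * cov["age"]
        with pytest.raises(ValueError, match="rank-deficient"):
            cc.ancova_group_test(self.y, self.g, cov)

    def test_parametric_p_agrees_with_permutation(self, rng):
        """F-test p tracks the group-label permutation distribution."""
        diffs = []
        for _ in range(20):
            n = 40
            cov = pd.DataFrame({"age": rng.uniform(16, 32, n),
                                "sex": rng.integers(0, 2, n)})
            g = rng.permutation(np.repeat([0.0, 1.0], n // 2))
            y = 0.05 * cov["age"].to_numpy() + 0.4 * g + rng.normal(0, 1, n)
            res = cc.ancova_group_test(y, g, cov)
            n_perm, hits = 2000, 0
            for _ in range(n_perm):
                gp = rng.permutation(g)
                hits += cc.ancova_group_test(y, gp, cov).statistic >= res.statistic
            perm_p = (1 + hits) / (1 + n_perm)
            diffs.append(perm_p - res.p_value)
        assert np.mean(np.abs(diffs)) < 0.02
        assert np.max(np.abs(diffs)) < 0.05


def mann_whitney_u_oracle(x, y):
    """Brute-force U: count pairwise wins (ties count half)."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += (xi > yi) + 0.5 * (xi == yi)
    return u


class TestContinuousComparison:
    def test_mann_whitney_matches_pairwise_count_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = cc.compare_groups_continuous(
            np.r_[x, y], np.r_[np.ones(3), np.zeros(3)], strategy="mann_whitney"
        )
        assert res.statistic == mann_whitney_u_oracle(x, y) == 0.0

    def test_identical_groups_not_significant(self):
        vals = np.r_[np.arange(6.0), np.arange(6.0)]
        g = np.r_[np.ones(6), np.zeros(6)]
        res = cc.compare_groups_continuous(vals, g, strategy="mann_whitney")
        assert res.p_value > 0.99

    def test_auto_gate_leaves_ancova_for_lognormal(self, rng):
        n = 60
        g = np.repeat([0.0, 1.0], n // 2)
        y = np.exp(rng.normal(0, 1.2, n) + 0.3 * g)
        res = cc.compare_groups_continuous(y, g, strategy="auto")
        assert res.test_name in ("log_ancova", "mann_whitney")

    def test_auto_gate_keeps_ancova_for_gaussian(self, rng):
        n = 60
        g = np.repeat([0.0, 1.0], n // 2)
        y = rng.normal(0, 1, n) + 0.3 * g
        res = cc.compare_groups_continuous(y, g, strategy="auto")
        assert res.test_name == "ancova"

    def test_log_branch_rejects_nonpositive(self):
        g = np.repeat([0.0, 1.0], 5)
        y = np.r_[np.arange(-1.0, 4.0), np.arange(1.0, 6.0)]
        with pytest.raises(ValueError, match="positive"):
            cc.compare_groups_continuous(y, g, strategy="log_ancova")


def test_group_comparison_table_schema(small_cohort):
    cohort = small_cohort[0]
    table = cc.group_comparison_table(cohort, cc.BRIEF_SCALES[:3])
    assert list(table.columns) == ["outcome", "test_name", "statistic", "df",
                                   "p", "n"]
    assert len(table) == 3
    assert table["p"].between(0, 1).all()
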