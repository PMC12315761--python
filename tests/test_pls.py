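"""Behavioural PLS correlation: fit, permutation, bootstrap, split-half."""

import numpy as np
import pandas as pd
import pytest

import chdcortex as cc
from chdcortex.pls import (PreprocessingError, zscore_columns,
                           results_tables)


def planted_blocks(n, rho, seed=0, p_x=6, p_y=4):
    """One latent factor couples the first 3 X and first 2 Y columns."""
    rng = np.random.default_rng(seed)
    f = rng.normal(0, 1, n)
    X = rng.normal(0, 1, (n, p_x))
    Y = rng.normal(0, 1, (n, p_y))
    for j, w in zip(range(3), (1.0, 0.8, 0.6)):
        X[:, j] += rho * w * f / np.sqrt(1 - rho**2)
    for j, w in zip(range(2), (1.0, -0.9)):
        Y[:, j] += rho * w * f / np.sqrt(1 - rho**2)
    return zscore_columns(X), zscore_columns(Y)


def svd2x2_oracle(R):
    """Closed-form SVD of a 2x2 matrix via the eigenangle of R^T R."""
    M = R.T @ R
    theta = 0.5 * np.arctan2(2 * M[0, 1], M[0, 0] - M[1, 1])
    V = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    S = np.linalg.norm(R @ V, axis=0)
    if S[0] < S[1]:
        V = V[:, ::-1]
        S = S[::-1]
    U = (R @ V) / S
    return U, S, V


class TestDesignMatrices:
    def test_block_shapes_and_coding(self, prepared_fit):
        cohort, _, inp, fit, _ = prepared_fit
        brain, behavior, dropped = cc.build_design_matrices(
            cohort, fit.H, inp.column_labels
        )
        k = fit.W.shape[1]
        assert brain.X.shape[1] == 3 * k
        assert behavior.Y.shape[1] == 17
        assert behavior.column_labels[:5] == [
            "group", "age", "sex", "lesion", "maternal_education"
        ]
        # z-scored columns
        for M in (brain.X, behavior.Y):
            np.testing.assert_allclose(M.mean(axis=0), 0.0, atol=1e-10)
            np.testing.assert_allclose(M.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert dropped == []

    def test_twelve_components_give_36_brain_columns(self, rng):
        n, k = 30, 12
        ids = [f"s{i}" for i in range(n)]
        H = rng.uniform(0.1, 1.0, (k, 3 * n))
        labels = [(s, m) for m in cc.METRICS for s in ids]
        cohort = _toy_cohort(ids, rng)
        brain, behavior, _ = cc.build_design_matrices(cohort, H, labels)
        assert brain.X.shape == (n, 36)
        assert behavior.Y.shape == (n, 17)

    def test_missing_behavior_drops_subject(self, rng):
        ids = [f"s{i}" for i in range(12)]
        H = rng.uniform(0.1, 1.0, (3, 36))
        labels = [(s, m) for m in cc.METRICS for s in ids]
        cohort = _toy_cohort(ids, rng)
        cohort.loc[3, "brief_gec"] = np.nan
        brain, behavior, dropped = cc.build_design_matrices(cohort, H, labels)
        assert dropped == ["s3"]
        assert brain.X.shape[0] == 11


def _toy_cohort(ids, rng):
    n = len(ids)
    df = pd.DataFrame({
        "subject_id": ids,
        "group": rng.integers(0, 2, n),
        "age": rng.uniform(16, 32, n),
        "sex": rng.integers(0, 2, n),
        "lesion": rng.integers(0, 2, n),
        "maternal_education": rng.integers(0, 2, n),
    })
    for s in cc.BRIEF_SCALES:
        df[s] = rng.normal(50, 10, n)
    return df


class TestFit:
    def test_varexp_sums_to_one(self, rng):
        X = zscore_columns(rng.normal(0, 1, (40, 7)))
        Y = zscore_columns(rng.normal(0, 1, (40, 5)))
        res = cc.fit_bpls(X, Y)
        assert res.varexp.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(res.singular_values) <= 1e-12).all()

    def test_printed_lv_fractions_are_additive(self, rng):
        # under s^2 / sum(s^2), per-LV fractions add: 66.1% + 16.7% = 82.8%
        assert 66.1 + 16.7 == pytest.approx(82.8)
        X = zscore_columns(rng.normal(0, 1, (30, 6)))
        Y = zscore_columns(rng.normal(0, 1, (30, 4)))
        res = cc.fit_bpls(X, Y)
        assert res.varexp[:2].sum() == pytest.approx(
            (res.singular_values[:2] ** 2).sum()
            / (res.singular_values**2).sum()
        )

    def test_two_by_two_matches_closed_form_svd(self, rng):
        X = zscore_columns(rng.normal(0, 1, (50, 2)))
        Y = zscore_columns(0.6 * X[:, [1, 0]] + rng.normal(0, 1, (50, 2)))
        Y = zscore_columns(Y)
        res = cc.fit_bpls(X, Y)
        R = Y.T @ X / 49
        U, S, V = svd2x2_oracle(R)
        np.testing.assert_allclose(res.singular_values, S, atol=1e-8)
        for l in range(2):
            u, v = U[:, l], V[:, l]
            if u[np.argmax(np.abs(u))] < 0:
                u, v = -u, -v
            np.testing.assert_allclose(res.behavior_saliences[:, l], u,
                                       atol=1e-8)
            np.testing.assert_allclose(res.brain_saliences[:, l], v, atol=1e-8)

    def test_swapping_blocks_transposes_saliences(self, rng):
        X, Y = planted_blocks(60, 0.5, seed=3)
        f_xy = cc.fit_bpls(X, Y)
        f_yx = cc.fit_bpls(Y, X)
        L = f_xy.n_lv
        for l in range(L):
            a = f_xy.behavior_saliences[:, l]
            b = f_yx.brain_saliences[:, l]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_zero_variance_column_is_named(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X[:, 1] = 2.0
        Y = rng.normal(0, 1, (20, 2))
        with pytest.raises(PreprocessingError, match="colB"):
            cc.fit_bpls(X, Y, brain_labels=["colA", "colB", "colC"])

    def test_salience_recovery_on_planted_lv(self):
        X, Y = planted_blocks(150, 0.6, seed=11)
        res = cc.fit_bpls(X, Y)
        # planted loadings, normalized
        vx = np.zeros(6)
        vx[:3] = [1.0, 0.8, 0.6]
        vy = np.zeros(4)
        vy[:2] = [1.0, -0.9]
        vx /= np.linalg.norm(vx)
        vy /= np.linalg.norm(vy)
        cos_x = abs(res.brain_saliences[:, 0] @ vx)
        cos_y = abs(res.behavior_saliences[:, 0] @ vy)
        assert cos_x >= 0.9 and cos_y >= 0.9


class TestScores:
    def test_three_subject_hand_example(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        Y = np.array([[2.0], [0.0], [1.0]])
        res_v = np.array([[0.6], [0.8]])
        res_u = np.array([[1.0]])
        fake = cc.PlsResult(singular_values=np.array([1.0]),
                            brain_saliences=res_v, behavior_saliences=res_u,
                            varexp=np.array([1.0]), x_scores=None,
                            y_scores=None)
        xs, ys = cc.latent_scores(X, Y, fake)
        np.testing.assert_allclose(xs[:, 0], [0.6, 0.8, 1.4])
        np.testing.assert_allclose(ys[:, 0], [2.0, 0.0, 1.0])

    def test_row_permutation_permutes_scores(self, rng):
        X, Y = planted_blocks(40, 0.5, seed=5)
        res = cc.fit_bpls(X, Y)
        perm = rng.permutation(40)
        xs, ys = cc.latent_scores(X[perm], Y[perm], res)
        np.testing.assert_allclose(xs, res.x_scores[perm], atol=1e-12)
        np.testing.assert_allclose(ys, res.y_scores[perm], atol=1e-12)

    def test_first_lv_has_strongest_score_correlation(self):
        X, Y = planted_blocks(120, 0.6, seed=8)
        res = cc.fit_bpls(X, Y)
        corrs = [abs(np.corrcoef(res.x_scores[:, l], res.y_scores[:, l])[0, 1])
                 for l in range(res.n_lv)]
        assert corrs[0] == max(corrs)


class TestPermutation:
    def test_p_within_add_one_bounds(self, rng):
        X = zscore_columns(rng.normal(0, 1, (25, 4)))
        Y = zscore_columns(rng.normal(0, 1, (25, 3)))
        p = cc.permutation_pvalues(X, Y, n_perm=200, seed=0)
        assert (p >= 1 / 201).all() and (p <= 1.0).all()

    def test_strong_coupling_attains_add_one_minimum(self):
        X, Y = planted_blocks(100, 0.8, seed=2)
        p = cc.permutation_pvalues(X, Y, n_perm=1000, seed=0)
        assert p[0] == pytest.approx(1 / 1001)

    def test_reproducible_given_seed(self, rng):
        X, Y = planted_blocks(30, 0.4, seed=1)
        p1 = cc.permutation_pvalues(X, Y, n_perm=300, seed=9)
        p2 = cc.permutation_pvalues(X, Y, n_perm=300, seed=9)
        assert np.array_equal(p1, p2)

    def test_low_counts_warn(self, rng):
        X, Y = planted_blocks(20, 0.4, seed=1)
        with pytest.warns(UserWarning, match="n_perm"):
            cc.permutation_pvalues(X, Y, n_perm=50, seed=0)


class TestBootstrap:
    def test_ratio_sign_matches_salience_when_ci_excludes_zero(self):
        X, Y = planted_blocks(120, 0.6, seed=4)
        res = cc.bootstrap_saliences(X, Y, n_boot=300, seed=0)
        for sal, ratio, contrib in (
            (res.behavior_saliences, res.bootstrap_ratios_behavior,
             res.contributing_behavior),
            (res.brain_saliences, res.bootstrap_ratios_brain,
             res.contributing_brain),
        ):
            hit = contrib & (sal != 0)
            assert np.all(np.sign(ratio[hit]) == np.sign(sal[hit]))

    def test_degenerate_bootstrap_has_zero_width_ci(self):
        X, Y = planted_blocks(40, 0.5, seed=6)
        res = cc.bootstrap_saliences(
            X, Y, n_boot=50, seed=0,
            resampler=lambda rng, n: np.arange(n),
        )
        width = res.ci95_behavior[..., 1] - res.ci95_behavior[..., 0]
        np.testing.assert_allclose(width, 0.0, atol=1e-12)

    def test_contributing_flag_calibration(self):
        """Planted variables are flagged, pure-noise variables are not."""
        hits_planted, hits_noise = 0, 0
        reps = 60
        for r in range(reps):
            X, Y = planted_blocks(150, 0.6, seed=1000 + r)
            res = cc.bootstrap_saliences(X, Y, n_boot=200, seed=r)
            hits_planted += bool(res.contributing_behavior[0, 0])
            hits_noise += bool(res.contributing_behavior[3, 0])
        assert hits_planted / reps >= 0.95
        assert hits_noise / reps <= 0.10


class TestSplitHalfStability:
    def test_strong_coupling_reproducible_across_halves(self):
        X, Y = planted_blocks(100, 0.8, seed=3)
        p_left, p_right = cc.split_half_singular_stability(
            X, Y, n_splits=20, n_perm=99, seed=0
        )
        assert p_left.shape == p_right.shape == (min(X.shape[1], Y.shape[1]),)
        assert p_left[0] <= 0.05 and p_right[0] <= 0.05

    def test_reports_two_sided_schema_per_lv(self, rng):
        X, Y = planted_blocks(40, 0.4, seed=9)
        p_left, p_right = cc.split_half_singular_stability(
            X, Y, n_splits=10, n_perm=49, seed=1
        )
        assert (p_left > 0).all() and (p_left <= 1).all()
        assert (p_right > 0).all() and (p_right <= 1).all()

    def test_null_rejection_rate_near_nominal(self):
        rejections = 0
        sims = 200
        for s in range(sims):
            rng = np.random.default_rng(5000 + s)
            X = zscore_columns(rng.normal(0, 1, (40, 5)))
            Y = zscore_columns(rng.normal(0, 1, (40, 4)))
            p_left, _ = cc.split_half_singular_stability(
                X, Y, n_splits=6, n_perm=39, seed=s
            )
            rejections += p_left[0] <= 0.05
        assert abs(rejections / sims - 0.05) <= 0.03

    def test_too_few_subjects_raises(self, rng):
        X, Y = planted_blocks(6, 0.4, seed=0)
        with pytest.raises(ValueError, match="at least 8"):
            cc.split_half_singular_stability(X, Y, n_splits=5, n_perm=20)


def test_results_tables_schema():
    X, Y = planted_blocks(50, 0.5, seed=12)
    res = cc.fit_bpls(X, Y, brain_labels=[f"b{i}" for i in range(6)],
                      behavior_labels=[f"y{i}" for i in range(4)])
    res.perm_p = cc.permutation_pvalues(X, Y, n_perm=100, seed=0)
    res = cc.bootstrap_saliences(X, Y, n_boot=100, seed=0, result=res)
    lv, sal, scores = results_tables(res)
    assert {"lv", "singular_value", "varexp", "perm_p"} <= set(lv.columns)
    assert {"side", "variable", "salience", "bootstrap_ratio",
            "contributing"} <= set(sal.columns)
    assert len(scores) == 50
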