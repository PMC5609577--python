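"""Calibration engine unit tests with independent oracles."""

import numpy as np
import pytest
from scipy import stats

from lipopls.chemometrics import (
    decide_sqrt_transform,
    detect_outliers,
    fit_pls,
    kennard_stone,
    pca_scores,
    permutation_test,
    select_n_lv,
    select_representative,
    validation_metrics,
)


class TestPca:
    def test_line_explains_everything(self):
        t = np.linspace(-1, 1, 20)
        X = np.column_stack([t, 2 * t])
        s = pca_scores(X, 1)
        # PC1 carries all the variance of perfectly collinear data
        assert np.allclose(np.abs(s[:, 0]), np.sqrt(5) * np.abs(t))

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(15, 4))
        s = pca_scores(X, 4)
        # scores preserve centered geometry: pairwise distances match
        Xc = X - X.mean(0)
        d1 = np.linalg.norm(Xc[:, None] - Xc[None], axis=2)
        d2 = np.linalg.norm(s[:, None] - s[None], axis=2)
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(30, 6))
        np.testing.assert_array_equal(pca_scores(X, 3), pca_scores(X.copy(), 3))

    def test_k_beyond_rank_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="rank"):
            pca_scores(X, 2)


class TestSelectRepresentative:
    def test_even_spread_on_grid(self):
        scores = np.arange(10.0)
        sel = select_representative(scores, 5)
        assert len(sel) == 5
        assert 0 in sel and 9 in sel
        gaps = np.diff(np.sort(scores[sel]))
        assert gaps.max() <= 3

    def test_identity_when_m_equals_n(self):
        np.testing.assert_array_equal(select_representative(np.arange(7.0), 7), np.arange(7))

    def test_no_duplicates_with_tied_scores(self):
        sel = select_representative(np.array([0.0, 0, 0, 1, 1, 2]), 4)
        assert len(sel) == len(set(sel))

    def test_m_too_small_rejected(self):
        with pytest.raises(ValueError):
            select_representative(np.arange(5.0), 1)


class TestOutliers:
    def test_null_calibration(self, rng):
        X = rng.normal(size=(240, 20))
        scores = pca_scores(X, 2)
        subjects = np.repeat([f"S{i}" for i in range(40)], 6)
        excluded, flagged = detect_outliers(scores, subjects)
        assert 0 <= flagged.mean() < 0.04  # ~1% expected at the 99% limit
        assert excluded == set()

    def test_planted_subject_excluded(self, rng):
        X = rng.normal(size=(240, 20))
        X[:6] *= 10.0  # one subject's six samples blown up
        subjects = np.repeat([f"S{i}" for i in range(40)], 6)
        excluded, flagged = detect_outliers(pca_scores(X, 2), subjects)
        assert excluded == {"S0"}
        assert flagged[:6].sum() >= 4  # majority of the subject's samples

    def test_identical_samples_none_flagged(self):
        scores = np.zeros((30, 2))
        subjects = np.repeat([f"S{i}" for i in range(5)], 6)
        excluded, flagged = detect_outliers(scores, subjects)
        assert excluded == set() and not flagged.any()


def kennard_stone_oracle(X, m):
    """Literal max-min selection by exhaustive scanning (small n only)."""
    n = len(X)
    D = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(n)] for i in range(n)])
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best:
                best, pair = D[i, j], (i, j)
    sel = list(pair)
    while len(sel) < m:
        cand_best, cand = -1.0, None
        for i in range(n):
            if i in sel:
                continue
            dmin = min(D[i, j] for j in sel)
            if dmin > cand_best:
                cand_best, cand = dmin, i
        sel.append(cand)
    return sel


class TestKennardStone:
    def test_matches_exhaustive_oracle_on_plane(self, rng):
        for _ in range(5):
            X = rng.normal(size=(5, 2))
            train, _ = kennard_stone(X, 4)
            assert list(train) == kennard_stone_oracle(X, 4)

    def test_split_sizes_122_80(self, rng):
        X = rng.normal(size=(122, 10))
        train, test = kennard_stone(X, 80)
        assert len(train) == 80 and len(test) == 42
        assert len(np.intersect1d(train, test)) == 0

    def test_m_equals_n_empty_test(self, rng):
        X = rng.normal(size=(6, 2))
        train, test = kennard_stone(X, 6)
        assert len(test) == 0 and sorted(train) == list(range(6))

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            kennard_stone(rng.normal(size=(5, 2)), 1)


class TestSqrtDecision:
    def test_lognormal_is_transformed(self):
        y = np.random.default_rng(11).lognormal(0.0, 0.8, 80)
        assert stats.skew(y) > 1  # sanity on the instance
        assert decide_sqrt_transform(y) is True

    def test_symmetric_is_not(self):
        y = np.abs(np.random.default_rng(2).normal(10.0, 0.5, 80))
        assert abs(stats.skew(y)) < 1
        assert decide_sqrt_transform(y) is False

    def test_constant_and_negative(self):
        assert decide_sqrt_transform(np.full(10, 3.0)) is False
        with pytest.raises(ValueError):
            decide_sqrt_transform(np.array([-1.0, 2.0]))


class TestPls:
    def test_exact_recovery_single_orthogonal_column(self, rng):
        # orthogonal zero-mean columns: y linear in one column is a
        # rank-1 problem solved exactly by a single component
        raw = rng.normal(size=(20, 5))
        Xc = raw - raw.mean(0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        X = U * s
        y = 3.0 * X[:, 2] + 1.0
        met = validation_metrics(y, np.ravel(fit_pls(X, y, 1).predict(X)[0]))
        assert met["RMSE"] == pytest.approx(0, abs=1e-8)
        assert met["R"] == pytest.approx(1, abs=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        m = fit_pls(X, y, 4)
        yhat, _ = m.predict(X)
        Xd = np.column_stack([np.ones(12), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        np.testing.assert_allclose(np.ravel(yhat), Xd @ beta, atol=1e-8)

    def test_first_weight_is_cross_covariance(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        m = fit_pls(X, y, 1)
        Xc = X - X.mean(0)
        yc = y - y.mean()
        w = Xc.T @ yc
        cos = (m.coef @ w) / (np.linalg.norm(m.coef) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(scale=0.1, size=25)
        ours, _ = fit_pls(X, y, 4).predict(X)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y).predict(X)
        np.testing.assert_allclose(np.ravel(ours), np.ravel(ref), atol=1e-8)

    def test_mean_spectrum_predicts_y_mean(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        for a in (1, 3, 5):
            m = fit_pls(X, y, a)
            yhat, _ = m.predict(X.mean(0)[None, :])
            assert np.ravel(yhat)[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_n_lv_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.normal(size=10), 4)


class TestSelectNLv:
    def test_noiseless_rank_one(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, rng.normal(size=6))  # rank-1 design
        y = 2.0 * t
        assert select_n_lv(X, y, (1, 8), seed=0) == 1

    def test_recovers_three_factor_signal(self, rng):
        n = 80
        T = rng.normal(size=(n, 3))
        P = rng.normal(size=(3, 40))
        X = T @ P + rng.normal(scale=0.05, size=(n, 40))
        y = T @ np.array([1.0, -2.0, 1.5]) + rng.normal(scale=0.05, size=n)
        picked = select_n_lv(X, y, (1, 10), seed=3)
        assert 2 <= picked <= 4

    def test_within_range_and_degenerate_y(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        assert 1 <= select_n_lv(X, y, (1, 15), seed=1) <= 15
        with pytest.raises(ValueError, match="variance"):
            select_n_lv(X, np.ones(40), (1, 5), seed=1)


class TestPermutation:
    def test_strong_signal_hits_floor(self, rng):
        X = rng.normal(size=(40, 10))
        y = X @ rng.normal(size=10)
        res = permutation_test(X, y, n_lv=3, B=99, seed=5)
        assert res.p == pytest.approx(1 / 100)
        assert len(res.null_stats) == 99
        assert res.observed_stat > max(res.null_stats)

    def test_p_floor_is_one_over_b_plus_one(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5)
        for B in (19, 99):
            res = permutation_test(X, y, n_lv=2, B=B, seed=0)
            assert res.p >= 1 / (B + 1)

    def test_significance_threshold_needs_beating_all_nulls(self):
        # with the add-one estimator, p < 0.001 at B=1000 iff observed
        # exceeds every null statistic
        null = np.zeros(1000)
        observed = 1.0
        p = (int((null >= observed).sum()) + 1) / 1001
        assert p < 0.001
        null[0] = 2.0
        p = (int((null >= observed).sum()) + 1) / 1001
        assert p >= 0.001


class TestValidationMetrics:
    def test_perfect_prediction(self):
        m = validation_metrics([1.0, 2, 3], [1.0, 2, 3])
        assert m["Q2"] == 1 and m["RMSE"] == 0 and m["CV_pct"] == 0
        assert m["R"] == pytest.approx(1, abs=1e-12)

    def test_hand_computed_example(self):
        m = validation_metrics([1.0, 2, 3], [1.0, 2, 4])
        assert m["RMSE"] == pytest.approx(np.sqrt(1 / 3))
        assert m["Q2"] == pytest.approx(0.5)
        assert m["CV_pct"] == pytest.approx(100 * np.sqrt(1 / 3) / 2)

    def test_mean_predictor_is_zero(self, rng):
        y = rng.normal(10, 2, size=25)
        m = validation_metrics(y, np.full(25, y.mean()))
        assert m["Q2"] == pytest.approx(0, abs=1e-12)

    def test_q2_never_exceeds_one_and_rejects_constant(self, rng):
        y = rng.normal(size=30)
        yhat = rng.normal(size=30)
        assert validation_metrics(y, yhat)["Q2"] <= 1
        with pytest.raises(ValueError, match="variance"):
            validation_metrics(np.ones(5), rng.normal(size=5))
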