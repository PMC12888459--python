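"""NIPALS PLS1/OPLS, VIP, Q², permutation test and PCA."""

import warnings

import numpy as np
import pytest

from specscreen import (cross_validate_q2, fit_opls, fit_oplsda, fit_pls1,
                        pca, permutation_test, vip)
from specscreen.simulate import SimConfig, simulate_dataset, group_mean_table
from specscreen.tables import ValidationError, standardize_peaks


class TestPLS1:
    def test_single_column_equal_to_y_fits_exactly(self, rng):
        y = rng.normal(size=8)
        m = fit_pls1(y[:, None], y, n_comp=1)
        assert m.r2y == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(m.fitted(), y, atol=1e-10)

    def test_orthogonal_response_explains_nothing(self):
        # X columns constructed orthogonal to y (all centered)
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x1 = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        x1 = x1 - x1 @ y / (y @ y) * y
        x2 = np.array([0.0, 1.0, 0.0, -1.0, 1.0, -1.0])
        x2 = x2 - x2 @ y / (y @ y) * y
        with pytest.warns(UserWarning, match="exhausted"):
            m = fit_pls1(np.column_stack([x1, x2]), y, n_comp=1, scale=False)
        assert abs(m.r2y) < 1e-10

    def test_noiseless_linear_recovery(self, rng):
        X = rng.normal(size=(10, 5))
        beta = rng.normal(size=5)
        y = X @ beta
        m = fit_pls1(X, y, n_comp=5)
        assert m.r2y == pytest.approx(1.0, abs=1e-8)

    def test_prediction_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(12, 6))
        y = X @ rng.normal(size=6) + 0.3 * rng.normal(size=12)
        m = fit_pls1(X, y, n_comp=3)
        ref = sklearn.PLSRegression(n_components=3, scale=True).fit(X, y)
        X_new = rng.normal(size=(5, 6))
        np.testing.assert_allclose(m.predict(X_new),
                                   ref.predict(X_new).ravel(), atol=1e-8)

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(6, 3))
        with pytest.raises(ValidationError):
            fit_pls1(X, np.ones(6), n_comp=1)       # zero-variance y
        with pytest.raises(ValidationError):
            fit_pls1(X, rng.normal(size=6), n_comp=5)  # n_comp > rank


class TestOPLS:
    def test_zero_orthogonal_components_reduce_to_pls1(self, rng):
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        m_opls = fit_opls(X, y, n_orth=0)
        m_pls = fit_pls1(X, y, n_comp=1)
        np.testing.assert_allclose(m_opls.fitted(), m_pls.fitted(), atol=1e-10)
        X_new = rng.normal(size=(4, 6))
        np.testing.assert_allclose(m_opls.predict(X_new), m_pls.predict(X_new),
                                   atol=1e-10)

    def test_orthogonal_block_is_captured(self):
        # x1 mixes a y-orthogonal structure z into the predictive loading;
        # the orthogonal component must strip it out
        y = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        z = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])  # z ⟂ y by construction
        X = np.column_stack([y + z, y])
        m = fit_opls(X, y, n_orth=1, scale=False)
        assert m.n_orth == 1
        r = np.corrcoef(m.t[:, 0], y)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)
        # orthogonal score captures z and stays uncorrelated with y
        assert abs(np.corrcoef(m.t_orth[:, 0], y)[0, 1]) < 1e-6
        assert abs(np.corrcoef(m.t_orth[:, 0], z)[0, 1]) == pytest.approx(
            1.0, abs=1e-6)

    def test_predictive_and_orthogonal_scores_orthogonal(self, rng):
        X = rng.normal(size=(14, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=14)
        m = fit_opls(X, y, n_orth=3)
        for a in range(m.n_orth):
            assert abs(m.t[:, 0] @ m.t_orth[:, a]) < 1e-8

    def test_early_stop_when_no_orthogonal_variation(self, rng):
        y = rng.normal(size=7)
        with pytest.warns(UserWarning, match="orthogonal"):
            m = fit_opls(y[:, None], y, n_orth=2)
        assert m.n_orth < 2


class TestVIP:
    def test_single_variable_has_unit_vip(self, rng):
        y = rng.normal(size=9)
        m = fit_opls(y[:, None], y, n_orth=0)
        assert vip(m).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_informative_above_noise_below_one(self, rng):
        y = np.tile([1.0, -1.0], 8)
        noise = rng.normal(size=16)
        noise -= noise @ y / (y @ y) * y  # strictly uninformative
        m = fit_opls(np.column_stack([y, noise]), y, n_orth=0)
        v = vip(m)
        assert v.iloc[0] > 1 > v.iloc[1]

    @pytest.mark.parametrize("mode", ["predictive", "total"])
    def test_mean_square_identity(self, rng, mode):
        X = rng.normal(size=(11, 7))
        y = X @ rng.normal(size=7) + rng.normal(size=11)
        m = fit_opls(X, y, n_orth=2)
        assert (vip(m, mode=mode) ** 2).mean() == pytest.approx(1.0, abs=1e-9)
        m2 = fit_pls1(X, y, n_comp=3)
        assert (vip(m2) ** 2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_vip_screen_recovers_planted_actives(self):
        # generator defaults (12 groups, 5 actives, |β|=1): VIP ≥ 1 screening
        cfg = SimConfig(seed=0)
        table, panel, truth = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = standardize_peaks(group_mean_table(table,
                                                     truth.replicate_groups))
        hits = []
        for ind in panel.indicator_ids:
            m = fit_opls(std.areas.T, panel.indicator(ind), n_orth=1)
            v = vip(m)
            screened = set(v.index[v >= 1.0])
            hits.append(len(screened & set(truth.active_ids)) / cfg.n_active)
        assert np.mean(hits) >= 0.8


class TestCrossValidation:
    def test_noiseless_linear_gives_high_q2(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5)
        assert cross_validate_q2(X, y, folds=7, n_orth=1) > 0.99

    def test_shuffled_response_gives_nonpositive_q2_in_expectation(self, rng):
        X = rng.normal(size=(12, 5))
        q2s = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                y = rng.permutation(np.arange(12, dtype=float))
                q2s.append(cross_validate_q2(X, y, folds=4, n_orth=0))
        assert np.mean(q2s) < 0

    def test_folds_above_n_degrade_to_loo_with_warning(self, rng):
        y = rng.normal(size=5)
        with pytest.warns(UserWarning, match="leave-one-out"):
            q2 = cross_validate_q2(y[:, None], y, folds=9, n_orth=0)
        assert q2 > 0.9

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValidationError):
            cross_validate_q2(rng.normal(size=(2, 2)), np.array([1.0, 2.0]))


class TestPermutationTest:
    def test_predictive_response_never_exceeded(self, rng):
        X = rng.normal(size=(16, 6))
        y = X @ rng.normal(size=6)
        rep = permutation_test(X, y, n_perm=50, seed=3, folds=4)
        assert rep.n_exceed == 0
        # one predictive + one orthogonal component on a 6-dim exact linear
        # response: high but not perfect predictive power
        assert rep.q2 > 0.5

    def test_random_response_is_unexceptional(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        rep = permutation_test(X, y, n_perm=60, seed=4, folds=4)
        # original Q² sits inside the permuted distribution
        lo, hi = np.quantile(rep.q2_perm, [0.01, 0.99])
        assert lo - 0.5 < rep.q2 < hi + 0.5
        assert rep.n_exceed > 0

    def test_fixed_seed_is_bit_reproducible(self, rng):
        X = rng.normal(size=(10, 4))
        y = X @ np.ones(4) + rng.normal(size=10)
        r1 = permutation_test(X, y, n_perm=20, seed=7, folds=3)
        r2 = permutation_test(X, y, n_perm=20, seed=7, folds=3)
        np.testing.assert_array_equal(r1.q2_perm, r2.q2_perm)
        np.testing.assert_array_equal(r1.r2y_perm, r2.r2y_perm)


class TestOPLSDA:
    def test_separated_clusters_have_disjoint_scores(self, rng):
        a = rng.normal(size=(10, 4)) + np.array([4.0, 0, 0, 0])
        b = rng.normal(size=(10, 4)) - np.array([4.0, 0, 0, 0])
        X = np.vstack([a, b])
        labels = ["A"] * 10 + ["B"] * 10
        m = fit_oplsda(X, labels, n_orth=1)
        t = m.t[:, 0]
        assert max(t[:10]) < min(t[10:]) or min(t[:10]) > max(t[10:])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_oplsda(rng.normal(size=(4, 2)), ["A"] * 4)

    def test_multiclass_returns_one_vs_all_models(self, rng):
        X = rng.normal(size=(9, 3))
        models = fit_oplsda(X, ["A", "B", "C"] * 3, n_orth=0)
        assert set(models) == {"A", "B", "C"}


class TestPCA:
    def test_rank_one_data_fully_explained_by_first_component(self, rng):
        t = rng.normal(size=10)
        direction = np.array([1.0, 2.0, -1.0])
        X = np.outer(t, direction)
        res = pca(X, n_comp=2)
        assert res.r2x[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self, rng):
        res = pca(rng.normal(size=(9, 5)), n_comp=3)
        g = res.scores.T @ res.scores
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-8

    def test_r2x_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(8, 5))
        res = pca(X, n_comp=4)
        xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        np.testing.assert_allclose(res.r2x, eigvals[:4] / eigvals.sum(),
                                   atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValidationError):
            pca(rng.normal(size=(4, 5)), n_comp=4)
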