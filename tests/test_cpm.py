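"""CPM engine: selection, inner tuning, nested LOOCV, leakage guards."""

import numpy as np
import pytest
from scipy import stats

from dfcalff import (CpmConfig, CpmRegressor, evaluate_association,
                     inner_loocv_optimize, nested_loocv, select_features)
from dfcalff.cpm import (EmptySelectionError, _svr_fit_predict,
                         correlation_pvalues)

SHORT_GRID = tuple(np.round(np.arange(1, 51) * 0.001, 3))


def _signal_matrix(rng, n=30, L=20, strength=1.5, n_signal=1):
    y = rng.uniform(6, 29, n)
    X = rng.standard_normal((n, L))
    X[:, :n_signal] += (strength * (y - y.mean()) / y.std())[:, None]
    return X, y


class TestCorrelationPvalues:
    def test_matches_scipy_pearsonr(self, rng):
        X = rng.standard_normal((25, 12))
        y = rng.standard_normal(25)
        r, p = correlation_pvalues(X, y)
        for k in range(12):
            ref = stats.pearsonr(X[:, k], y)
            assert r[k] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[k] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlation_pvalues(rng.standard_normal((10, 3)), np.ones(10))


class TestSelectFeatures:
    def test_perfect_correlate_selected_with_positive_sign(self, rng):
        y = rng.uniform(0, 10, 20)
        X = rng.standard_normal((20, 10))
        X[:, 4] = y
        idx, signs = select_features(X, y, 0.001)
        assert 4 in idx
        assert signs[list(idx).index(4)] == 1

    def test_loose_threshold_selects_everything(self, rng):
        X = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        idx, _ = select_features(X, y, 0.999999)
        assert len(idx) == 8

    def test_matches_bruteforce_loop(self, rng):
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        idx, signs = select_features(X, y, 0.01)
        expected = [k for k in range(20)
                    if stats.pearsonr(X[:, k], y).pvalue < 0.01]
        assert list(idx) == expected
        for k, s in zip(idx, signs):
            assert s == np.sign(stats.pearsonr(X[:, k], y).statistic)

    def test_sign_restricted_modes(self, rng):
        y = rng.uniform(0, 10, 25)
        X = rng.standard_normal((25, 6))
        X[:, 0] = y
        X[:, 1] = -y
        pos, _ = select_features(X, y, 0.001, "positive_only")
        neg, _ = select_features(X, y, 0.001, "negative_only")
        assert 0 in pos and 1 not in pos
        assert 1 in neg and 0 not in neg


class TestInnerLoocv:
    def test_perfect_feature_gives_high_inner_r(self, rng):
        y = rng.uniform(6, 29, 30)
        X = rng.standard_normal((30, 20))
        X[:, 0] = (y - y.mean()) / y.std()
        best_p, inner_r = inner_loocv_optimize(X, y, CpmConfig(p_grid=SHORT_GRID))
        assert np.nanmax(inner_r) >= 0.95

    def test_tie_breaks_to_smallest_threshold(self, rng):
        """A single dominant feature (every other p-value far above the
        grid) makes all grid points equivalent; the smallest must win."""
        y = np.linspace(0, 10, 12)
        X = np.column_stack([y + 0.01 * np.sin(np.arange(12)),
                             np.tile([1.0, -1.0], 6) * 0.001 + 7])
        X[:, 1] += 1e-6 * np.arange(12) ** 2  # non-constant, uninformative
        best_p, inner_r = inner_loocv_optimize(X, y, CpmConfig(p_grid=SHORT_GRID))
        valid = np.flatnonzero(~np.isnan(inner_r))
        assert np.allclose(inner_r[valid], inner_r[valid][0], atol=1e-12)
        assert best_p == SHORT_GRID[valid[0]]

    def test_permuted_scores_give_null_inner_r(self, rng):
        """With the score-feature alignment destroyed, the tuned inner
        association stays inside the permutation null band."""
        X, y = _signal_matrix(rng, n=16, L=200, strength=2.0, n_signal=3)
        grid = tuple(np.round(np.arange(1, 6) * 0.01, 3))
        y_perm = rng.permutation(y)
        _, inner_r = inner_loocv_optimize(X, y_perm, CpmConfig(p_grid=grid))
        null = []
        for _ in range(20):
            _, ir = inner_loocv_optimize(
                X, rng.permutation(y), CpmConfig(p_grid=grid))
            null.append(np.nanmax(ir))
        assert np.nanmax(inner_r) <= max(null) + 0.1


class TestNestedLoocv:
    def test_perfect_feature_recovers_score(self, rng):
        y = rng.uniform(6, 29, 14)
        X = rng.standard_normal((14, 10))
        X[:, 3] = y
        result = nested_loocv(X, CpmConfig(p_grid=SHORT_GRID), scores=y)
        assert result.association_r > 0.99
        assert len(result.folds) == 14

    def test_deterministic_rerun(self, rng):
        X, y = _signal_matrix(rng, n=16, strength=2.0)
        a = nested_loocv(X, CpmConfig(p_grid=SHORT_GRID), scores=y)
        b = nested_loocv(X, CpmConfig(p_grid=SHORT_GRID), scores=y)
        np.testing.assert_array_equal(a.predictions, b.predictions)
        assert a.association_r == b.association_r
        assert [f.chosen_p for f in a.folds] == [f.chosen_p for f in b.folds]

    def test_fast_path_matches_naive_reference(self, rng):
        """The pair-shared inner loop must reproduce the naive nested loop
        (per-outer-fold inner optimization, per-threshold re-selection)."""
        X, y = _signal_matrix(rng, n=13, L=25, strength=1.8, n_signal=3)
        config = CpmConfig(p_grid=SHORT_GRID)
        fast = nested_loocv(X, config, scores=y)
        preds = np.empty(13)
        for h in range(13):
            tr = np.ones(13, dtype=bool)
            tr[h] = False
            best_p, _ = inner_loocv_optimize(X[tr], y[tr], config)
            assert best_p == fast.folds[h].chosen_p
            model = CpmRegressor(p_threshold=best_p).fit(X[tr], y[tr])
            preds[h] = model.predict(X[h][None, :])[0]
        np.testing.assert_allclose(fast.predictions, preds, atol=1e-8)

    def test_leakage_canary_feature_never_selected(self, rng):
        """A feature informative only through the held-out subject must not
        be selected in that subject's fold."""
        X, y = _signal_matrix(rng, n=14, L=12, strength=2.5)
        canary = 11
        X[:, canary] = 0.0
        X[0, canary] = 50.0 * y[0]
        result = nested_loocv(X, CpmConfig(p_grid=SHORT_GRID), scores=y)
        assert canary not in result.folds[0].selected_links

    def test_all_noise_tiny_pool_raises_empty_selection(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))
        y = rng.uniform(0, 1, 10)
        with pytest.raises(EmptySelectionError):
            nested_loocv(X, CpmConfig(p_grid=(0.001, 0.002)), scores=y)


class TestCpmRegressor:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        X, y = _signal_matrix(rng, n=24, strength=2.0)
        model = CpmRegressor(p_threshold=0.05)
        cloned = clone(model)
        assert cloned.get_params()["p_threshold"] == 0.05
        model.fit(X, y)
        assert model.selected_links_.size > 0
        assert model.predict(X).shape == (24,)

    def test_fast_svr_path_matches_sklearn_svr(self, rng):
        from sklearn.svm import SVR

        X = rng.standard_normal((40, 8))
        y = rng.uniform(6, 29, 40)
        ref = SVR(kernel="linear", C=1.0, epsilon=0.0).fit(X, y)
        fast = _svr_fit_predict(X, y, X[:5], CpmConfig())
        np.testing.assert_allclose(fast, ref.predict(X[:5]), atol=1e-8)

    def test_empty_selection_raises(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.uniform(0, 1, 12)
        with pytest.raises(EmptySelectionError):
            CpmRegressor(p_threshold=1e-9).fit(X, y)


class TestEvaluateAssociation:
    def test_identity_and_negation(self, rng):
        y = rng.standard_normal(15)
        assert evaluate_association(y, y)[0] == pytest.approx(1.0)
        assert evaluate_association(-y, y)[0] == pytest.approx(-1.0)

    def test_p_matches_t_transform(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        r, p = evaluate_association(a, b)
        t = r * np.sqrt(8 / (1 - r ** 2))
        expected = 2 * stats.t.sf(abs(t), df=8)
        assert p == pytest.approx(expected, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            evaluate_association(np.ones(10), np.arange(10.0))


def test_null_calibration_association_centered_at_zero():
    """Over independent pure-noise cohorts the out-of-fold association r
    distribution is centered near zero."""
    rs = []
    for rep in range(12):
        rng = np.random.default_rng(1000 + rep)
        X = rng.standard_normal((16, 60))
        y = rng.uniform(6, 29, 16)
        try:
            res = nested_loocv(X, CpmConfig(p_grid=SHORT_GRID), scores=y)
            rs.append(res.association_r)
        except EmptySelectionError:
            continue
    assert len(rs) >= 6
    assert abs(np.mean(rs)) < 0.25
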