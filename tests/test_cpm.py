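import numpy as np
import pytest
from scipy import stats

from connfp import (
    CPMConfig,
    CPMRegressor,
    cpm_fold,
    predict_with_fixed_edges,
    prediction_permutation_test,
    run_cpm,
    run_svr,
)
from connfp.cpm import edgewise_correlation
from connfp.fingerprint import EdgeMask


@pytest.fixture
def noisy_single_signal(rng):
    """30 subjects, 50 edges; edge 7 equals y, the rest are noise."""
    X = rng.standard_normal((30, 50))
    y = rng.standard_normal(30)
    X[:, 7] = y
    return X, y


class TestEdgewiseSelection:
    def test_matches_t_distribution_oracle(self, rng):
        # independent oracle: per-edge scipy.stats.pearsonr
        X = rng.standard_normal((30, 20))
        y = rng.standard_normal(30)
        r, p = edgewise_correlation(X, y)
        for k in range(20):
            res = stats.pearsonr(X[:, k], y)
            assert r[k] == pytest.approx(res.statistic, abs=1e-12)
            assert p[k] == pytest.approx(res.pvalue, abs=1e-12)

    def test_perfect_single_feature_fold(self, noisy_single_signal):
        X, y = noisy_single_signal
        preds, sets = cpm_fold(X[:25], y[:25], X[25:], threshold_p=0.001)
        assert sets["positive"][7]
        # noiseless feature: test predictions recover held-out y exactly
        assert np.allclose(preds["positive"], y[25:], atol=1e-8)

    def test_sign_flip_swaps_sides(self, rng):
        X = rng.standard_normal((25, 30))
        y = X[:, 3] + 0.1 * rng.standard_normal(25)
        _, sets = cpm_fold(X, y, X[:2], threshold_p=0.01)
        _, sets_neg = cpm_fold(X, -y, X[:2], threshold_p=0.01)
        assert np.array_equal(sets["positive"], sets_neg["negative"])
        assert np.array_equal(sets["negative"], sets_neg["positive"])

    def test_threshold_monotonicity(self, rng):
        X = rng.standard_normal((40, 100))
        y = rng.standard_normal(40)
        sets = {
            thr: cpm_fold(X, y, X[:2], threshold_p=thr)[1]["positive"]
            for thr in (0.001, 0.01, 0.05)
        }
        assert np.all(sets[0.001] <= sets[0.01])
        assert np.all(sets[0.01] <= sets[0.05])

    def test_empty_selection_predicts_training_mean(self, rng):
        X = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        est = CPMRegressor(threshold_p=1e-12).fit(X, y)
        assert not est.pos_edges_.any() and not est.neg_edges_.any()
        assert np.allclose(est.predict(X[:4]), y.mean())

    def test_sklearn_contract(self, noisy_single_signal):
        X, y = noisy_single_signal
        est = CPMRegressor(threshold_p=0.05)
        assert est.get_params()["threshold_p"] == 0.05
        est.set_params(threshold_p=0.01).fit(X, y)
        assert est.pos_edges_.shape == (50,)
        from sklearn.model_selection import cross_val_score

        scores = cross_val_score(CPMRegressor(), X, y, cv=3)
        assert np.all(np.isfinite(scores))


class TestRunCPM:
    def test_constant_target_rejected(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="constant target"):
            run_cpm(X, np.ones(20), CPMConfig(k_folds=2, n_repeats=1, n_perm=0))

    def test_too_few_subjects_rejected(self, rng):
        X = rng.standard_normal((5, 10))
        y = rng.standard_normal(5)
        with pytest.raises(ValueError, match="fewer complete subjects"):
            run_cpm(X, y, CPMConfig(k_folds=10, n_repeats=1, n_perm=0))

    def test_missing_scores_dropped_case_by_case(self, rng):
        X = rng.standard_normal((25, 30))
        y = X[:, :3].sum(axis=1) + 0.2 * rng.standard_normal(25)
        y[3] = np.nan
        y[17] = np.nan
        res = run_cpm(
            X, y, CPMConfig(k_folds=5, n_repeats=3, n_perm=0, seed=0),
            subjects=[f"s{i}" for i in range(25)],
        )
        assert res.n_complete == 23
        assert "s3" not in res.subjects and "s17" not in res.subjects

    def test_reproducible_given_seed(self, rng):
        X = rng.standard_normal((22, 40))
        y = rng.standard_normal(22)
        cfg = CPMConfig(k_folds=5, n_repeats=4, n_perm=0, seed=9)
        a = run_cpm(X, y, cfg)
        b = run_cpm(X, y, cfg)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(
            a.selection_frequency["positive"], b.selection_frequency["positive"]
        )

    def test_no_test_set_leakage(self, rng):
        # perturbing a held-out subject's score never changes that subject's
        # prediction (selection and fitting use training folds only)
        X = rng.standard_normal((20, 30))
        y = X[:, 5] + 0.3 * rng.standard_normal(20)
        cfg = CPMConfig(k_folds=4, n_repeats=2, n_perm=0, seed=3)
        base = run_cpm(X, y, cfg)
        y2 = y.copy()
        y2[0] += 100.0
        alt = run_cpm(X, y2, cfg)
        # subject 0's prediction may only change through folds where it was
        # in training; find a repeat/fold layout independent check: predictions
        # for subject 0 come only from folds where 0 is in test, whose models
        # never saw y[0]
        assert alt.predictions[0] == pytest.approx(base.predictions[0])

    def test_fold_sizes_balanced(self):
        from sklearn.model_selection import KFold

        for n in (20, 23):
            sizes = [len(te) for _, te in KFold(5, shuffle=True, random_state=0).split(np.empty((n, 1)))]
            assert max(sizes) - min(sizes) <= 1


class TestFixedEdges:
    def test_superset_mask_retains_signal(self, rng):
        X = 0.1 * rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        X[:, 12] = y  # the sum over all edges is dominated by the signal edge
        mask = EdgeMask(bits=np.ones(40, dtype=bool))
        res = predict_with_fixed_edges(
            X, y, mask, CPMConfig(k_folds=5, n_repeats=5, n_perm=0, seed=1)
        )
        assert res.rho > 0.3

    def test_empty_mask_rejected(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="empty"):
            predict_with_fixed_edges(
                X, rng.standard_normal(20), np.zeros(10, dtype=bool),
                CPMConfig(k_folds=4, n_repeats=1, n_perm=0),
            )


class TestPermutationTest:
    def test_perfect_prediction_unbeatable(self):
        y = np.arange(10.0)
        p, perm = prediction_permutation_test(y, y, n_perm=1000, seed=0)
        assert p < 0.001
        assert perm.size == 1000

    def test_observed_below_all_permutations(self, rng):
        # anti-rank prediction: observed rho = -1 is below every shuffle a.s.
        y = np.arange(12.0)
        pred = -y
        p, _ = prediction_permutation_test(pred, y, n_perm=500, seed=1)
        assert p >= 0.99
        assert p <= 500 / 501

    def test_null_calibration(self, rng):
        # independent prediction: p should be uniform; rejection at 0.05
        # lands in a binomial band over 200 replicates
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            pred = rng.standard_normal(30)
            y = rng.standard_normal(30)
            p, _ = prediction_permutation_test(pred, y, n_perm=199, seed=i)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_permuted_statistics_are_valid_spearman_rhos(self, rng):
        pred = rng.standard_normal(25)
        y = rng.standard_normal(25)
        _, perm = prediction_permutation_test(pred, y, n_perm=50, seed=2)
        assert np.all(np.abs(perm) <= 1 + 1e-12)
        # the permuted statistic for the identity permutation would equal
        # scipy's Spearman rho; verify the statistic convention on a case
        # where the permutation is forced to be the identity (n_perm with a
        # 1-element domain is impossible, so check via direct recomputation)
        rho = stats.spearmanr(pred, y).statistic
        rp = stats.rankdata(pred)
        ry = stats.rankdata(y)
        manual = np.corrcoef(rp, ry)[0, 1]
        assert rho == pytest.approx(manual, abs=1e-12)


class TestSVR:
    def test_single_informative_edge_gets_top_weight(self, rng):
        X = 0.1 * rng.standard_normal((40, 30))
        y = rng.standard_normal(40)
        X[:, 4] = y
        res = run_svr(
            X, y, CPMConfig(k_folds=5, n_repeats=3, n_perm=0, seed=2), weight_pct=97
        )
        freq = res.selection_frequency["combined"]
        assert freq[4] == 1.0

    def test_shuffled_target_gives_no_stable_edges(self, rng):
        X = rng.standard_normal((30, 200))
        y = rng.permutation(rng.standard_normal(30))
        res = run_svr(
            X, y, CPMConfig(k_folds=5, n_repeats=4, n_perm=0, seed=4), weight_pct=99
        )
        freq = res.selection_frequency["combined"]
        assert freq.max() < 0.8
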