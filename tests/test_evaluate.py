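"""AUC, permutation KS, baseline scorers, delta-AUC aggregation, lasso boot."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroact.evaluate import (
    auc,
    delta_auc_summary,
    imputed_additive,
    knn_impute,
    ks_permutation_test,
    lasso_bootstrap,
    multiunit_glm_score,
    pc1_baseline,
    residualize_by_type,
    scaled_additive,
)
from neuroact.io import CountMatrix
from neuroact.simdata import simulate_ephys


def brute_force_auc(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def _linear_scorer(cm):
    x = cm.dense().astype(float)
    norm = np.log1p(1e4 * x / x.sum(axis=0))
    return norm[:5].mean(axis=0)


class TestKSPermutation:
    def test_identical_groups_give_zero_d(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(4, (20, 40))
        cm = CountMatrix(x, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(40)])
        s = _linear_scorer(cm)
        res = ks_permutation_test(s[:20], s[:20],
                                  CountMatrix(np.hstack([x[:, :20]] * 2),
                                              cm.gene_ids,
                                              [f"c{i}" for i in range(40)]),
                                  _linear_scorer, n_perm=19, seed=1)
        assert res.statistic == 0.0

    def test_disjoint_supports_give_d_one(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(4, (20, 30))
        cm = CountMatrix(x, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(30)])
        a = np.arange(15, dtype=float)
        b = a + 100.0
        res = ks_permutation_test(a, b, cm, _linear_scorer, n_perm=19, seed=2)
        assert res.statistic == 1.0

    def test_p_value_floor_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(4, (20, 30))
        cm = CountMatrix(x, [f"g{i}" for i in range(20)], [f"c{i}" for i in range(30)])
        res = ks_permutation_test(
            np.zeros(15), np.ones(15) * 50, cm, _linear_scorer, n_perm=19, seed=3
        )
        assert res.p_value >= 1 / 20

    def test_group_size_mismatch_errors(self):
        cm = CountMatrix(np.ones((3, 5), dtype=int), list("abc"),
                         [f"c{i}" for i in range(5)])
        with pytest.raises(ValueError):
            ks_permutation_test([0.1, 0.2], [0.3, 0.4], cm, _linear_scorer)


class TestScaledAdditive:
    def test_single_cell_zero_range_scores_zero(self):
        assert scaled_additive(np.array([[3.0, 5.0]])) == pytest.approx(0.0)

    def test_two_cells_one_gene(self):
        assert np.allclose(scaled_additive(np.array([[0.0], [5.0]])), [0.0, 1.0])

    def test_hand_computed_3x3(self):
        x = np.array([[0.0, 2.0, 1.0], [1.0, 2.0, 3.0], [2.0, 2.0, 5.0]])
        # gene scales: (0,.5,1), (0,0,0 zero range), (0,.5,1)
        assert np.allclose(scaled_additive(x), [0.0, 1.0, 2.0])

    def test_range_bounded_by_target_count(self):
        rng = np.random.default_rng(0)
        s = scaled_additive(rng.normal(size=(50, 7)))
        assert (s >= 0).all() and (s <= 7).all()


class TestPC1Baseline:
    def test_self_projection_matches_training_coordinates(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 5)) + np.outer(rng.normal(size=100), np.ones(5))
        proj = pc1_baseline(x, x)
        centered = x - x.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        expected = centered @ vt[0]
        r = np.corrcoef(proj, expected)[0, 1]
        assert abs(r) > 0.999999

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(2)
        f_train, f_test = rng.normal(size=300), rng.normal(size=200)
        w = rng.uniform(0.5, 1.5, 8)
        train = np.outer(f_train, w) + rng.normal(0, 0.3, (300, 8))
        test = np.outer(f_test, w) + rng.normal(0, 0.3, (200, 8))
        from scipy.stats import spearmanr

        rho = spearmanr(pc1_baseline(train, test), f_test).statistic
        assert abs(rho) >= 0.9

    def test_positive_orientation(self):
        rng = np.random.default_rng(3)
        train = np.outer(rng.normal(size=200), np.ones(4)) + rng.normal(0, 0.2, (200, 4))
        test = np.zeros((2, 4))
        test[1] += 5.0  # uniformly higher target expression
        proj = pc1_baseline(train, test)
        assert proj[1] > proj[0]

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pc1_baseline(np.ones((10, 3)), np.ones((2, 3)))


class TestImputedAdditive:
    def test_identity_imputer_equals_scaled_additive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 10))
        got = imputed_additive(x, range(3), imputer=lambda m: m)
        assert np.allclose(got, scaled_additive(x[:, :3]))

    def test_knn_one_is_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 10))
        assert np.allclose(knn_impute(x, k=1), x)

    def test_smoothing_improves_noisy_truth_correlation(self):
        rng = np.random.default_rng(6)
        wins = 0
        for trial in range(10):
            f = rng.normal(size=300)
            x = np.outer(f, np.ones(12)) + rng.normal(0, 2.0, (300, 12))
            raw = scaled_additive(x[:, :5])
            smooth = imputed_additive(x, range(5), k=15)
            wins += abs(np.corrcoef(smooth, f)[0, 1]) >= abs(np.corrcoef(raw, f)[0, 1])
        assert wins >= 7

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            imputed_additive(np.ones((10, 4)), [0], imputer=lambda m: m[:, :2])


class TestMultiunitGLM:
    def test_follows_perfectly_predictive_unit(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 200)
        train = np.column_stack([y + rng.normal(0, 0.01, 200), rng.normal(size=200)])
        test = np.column_stack([np.linspace(0, 1, 50), np.zeros(50)])
        s = multiunit_glm_score(train, y, test)
        assert (np.diff(s) > 0).all()

    def test_null_units_give_chance_auc(self):
        rng = np.random.default_rng(8)
        y_tr = rng.integers(0, 2, 2000)
        train = rng.normal(size=(2000, 2))
        y_te = rng.integers(0, 2, 2000)
        test = rng.normal(size=(2000, 2))
        s = multiunit_glm_score(train, y_tr, test)
        assert abs(auc(s, y_te) - 0.5) <= 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        tr, te = rng.normal(size=(100, 3)), rng.normal(size=(20, 3))
        assert np.array_equal(
            multiunit_glm_score(tr, y, te), multiunit_glm_score(tr, y, te)
        )


class TestDeltaAUC:
    def _rows(self):
        return pd.DataFrame(
            [
                ("bottleneck", "ds1", "g1", 0.9),
                ("bottleneck", "ds1", "g2", 0.8),
                ("bottleneck", "ds2", "g1", 0.7),
                ("other", "ds1", "g1", 0.8),
                ("other", "ds1", "g2", 0.5),
                ("other", "ds2", "g1", 0.5),
            ],
            columns=["method", "dataset", "grouping", "auc"],
        )

    def test_identical_method_gives_zero_deltas(self):
        rows = self._rows()
        clone = rows[rows["method"] == "bottleneck"].assign(method="clone")
        per_row, _, summary = delta_auc_summary(pd.concat([rows, clone]))
        assert np.allclose(
            per_row.loc[per_row["method"] == "clone", "delta_auc"], 0.0
        )

    def test_mean_of_per_dataset_means(self):
        # ds1 deltas (0.1, 0.3) -> 0.2; ds2 delta (0.2) -> 0.2; overall 0.2
        per_row, per_ds, summary = delta_auc_summary(self._rows())
        assert summary.loc[summary["method"] == "other", "mean_delta_auc"].iloc[0] == pytest.approx(0.2)

    def test_win_fraction(self):
        rows = self._rows()
        rows.loc[rows.index[-1], "auc"] = 0.95  # one loss for the reference
        _, _, summary = delta_auc_summary(rows)
        assert summary["win_fraction"].iloc[0] == pytest.approx(2 / 3)

    def test_row_order_invariance(self):
        rows = self._rows()
        _, _, s1 = delta_auc_summary(rows)
        _, _, s2 = delta_auc_summary(rows.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            s1.reset_index(drop=True), s2.reset_index(drop=True)
        )

    def test_missing_reference_errors(self):
        rows = self._rows()
        with pytest.raises(ValueError):
            delta_auc_summary(rows[rows["method"] != "bottleneck"])


class TestResidualize:
    def test_single_type_is_mean_centering(self):
        v = np.array([1.0, 2.0, 6.0])
        res, keep = residualize_by_type(v, ["t"] * 3)
        assert np.allclose(res, v - 3.0) and keep.all()

    def test_pure_type_means_residualize_to_zero(self):
        v = np.array([2.0, 2.0, 5.0, 5.0])
        res, _ = residualize_by_type(v, ["a", "a", "b", "b"])
        assert np.allclose(res, 0.0)

    def test_two_type_hand_computation(self):
        v = np.array([1.0, 3.0, 10.0, 14.0])
        res, _ = residualize_by_type(v, ["a", "a", "b", "b"])
        assert np.allclose(res, [-1.0, 1.0, -2.0, 2.0])

    def test_singleton_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res, keep = residualize_by_type([1.0, 2.0, 9.0], ["a", "a", "solo"])
        assert keep.tolist() == [True, True, False]
        assert np.isnan(res[2])


class TestLassoBootstrap:
    def test_planted_signs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.beta(2, 5, 2000)
        eph = simulate_ephys(a, seed=1)
        res = lasso_bootstrap(
            eph.drop(columns="neuron_type"), a, eph["neuron_type"],
            n_boot=300, seed=2,
        )
        t = res.table
        assert t.loc["tau", "significant"] and t.loc["tau", "mean_coef"] < 0
        assert (
            t.loc["input_resistance", "significant"]
            and t.loc["input_resistance", "mean_coef"] > 0
        )
        assert (
            t.loc["threshold_current", "significant"]
            and t.loc["threshold_current", "mean_coef"] < 0
        )

    def test_weight_scale_invariance(self):
        # multiplying all weights by a constant leaves a weighted lasso fit
        # unchanged; the pipeline normalizes weights to mean 1 internally
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = X @ [1.0, -0.5, 0.0] + rng.normal(0, 0.1, 100)
        w = rng.exponential(1.0, 100)
        c1 = Lasso(alpha=0.01).fit(X, y, sample_weight=w).coef_
        c2 = Lasso(alpha=0.01).fit(X, y, sample_weight=2 * w).coef_
        assert np.allclose(c1, c2, atol=1e-9)

    def test_null_features_rarely_significant(self):
        rng = np.random.default_rng(2)
        sig_counts = []
        for trial in range(5):
            scores = rng.beta(2, 5, 1000)
            eph = simulate_ephys(rng.beta(2, 5, 1000), seed=50 + trial)
            res = lasso_bootstrap(
                eph.drop(columns="neuron_type"), scores, eph["neuron_type"],
                n_boot=150, seed=trial,
            )
            sig_counts.append(int(res.table["significant"].sum()))
        assert sum(c == 0 for c in sig_counts) >= 4

    def test_missingness_filters(self):
        rng = np.random.default_rng(3)
        a = rng.beta(2, 5, 800)
        eph = simulate_ephys(a, seed=4)
        feats = eph.drop(columns="neuron_type").copy()
        feats["mostly_missing"] = np.nan  # dropped by the feature filter
        feats.iloc[:10, feats.columns.get_loc("tau")] = np.nan  # drops 10 cells
        res = lasso_bootstrap(
            feats, a, eph["neuron_type"], n_boot=120,
            missing_cell_threshold=500, seed=5,
        )
        assert "mostly_missing" not in res.table.index
        assert res.n_cells <= 790

    def test_small_n_boot_warns(self):
        rng = np.random.default_rng(6)
        a = rng.beta(2, 5, 300)
        eph = simulate_ephys(a, seed=7)
        with pytest.warns(UserWarning):
            lasso_bootstrap(
                eph.drop(columns="neuron_type"), a, eph["neuron_type"],
                n_boot=50, seed=8,
            )
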