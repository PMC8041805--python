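import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor

from editcode import features as ft
from editcode import model as mt
from editcode import shap_trees as shp
from oracles import brute_shapley, leaf_path_expectation


def make_matrix(X: np.ndarray, y: np.ndarray, positions=None, names=None) -> ft.FeatureMatrix:
    n, d = X.shape
    names = names or [f"f{k}" for k in range(d)]
    data = pd.DataFrame(X, columns=names)
    data.insert(0, "variant_id", [f"v{i}" for i in range(n)])
    data.insert(1, "row_position", positions if positions is not None else list(range(1, n + 1)))
    data.insert(2, "target_editing", y)
    data.insert(3, "label_edited", (y > np.median(y)).astype(float))
    return ft.FeatureMatrix(data=data, registry=ft.FeatureRegistry.from_columns(names))


def planted_matrix(seed=0, n=300, noise=0.02):
    # binary features so the planted linear rule is exactly tree-representable
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, 5)).astype(float)
    y = 0.6 * X[:, 0] - 0.3 * X[:, 1] + rng.normal(0, noise, size=n)
    return make_matrix(X, y), noise


def full_split(n, seed=0):
    return mt.make_position_splits(range(1, n + 1), seed=seed)


class TestPositionSplits:
    def test_fraction_counts(self):
        s = mt.make_position_splits(range(100), seed=5)
        counts = Counter(s.assignment.values())
        assert counts["train"] == 70
        assert counts["validation"] == 15
        assert counts["test"] == 15

    def test_co_mutated_share_split(self):
        for seed in range(10):
            s = mt.make_position_splits(range(20), [frozenset({3, 7})], seed=seed)
            assert s.assignment[3] == s.assignment[7]

    def test_transitive_grouping(self):
        s = mt.make_position_splits(
            range(10), [frozenset({1, 2}), frozenset({2, 3})], seed=0
        )
        assert s.assignment[1] == s.assignment[2] == s.assignment[3]

    def test_same_seed_identical(self):
        a = mt.make_position_splits(range(50), [frozenset({4, 9})], seed=11)
        b = mt.make_position_splits(range(50), [frozenset({4, 9})], seed=11)
        assert a.assignment == b.assignment

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mt.make_position_splits(range(10), fractions=(0.5, 0.2, 0.2))

    def test_oversized_group_warns(self):
        with pytest.warns(UserWarning, match="best-effort"):
            mt.make_position_splits(range(4), [frozenset({0, 1, 2, 3})], seed=0)


class TestLeakage:
    def test_no_leakage_holds(self):
        m, _ = planted_matrix()
        s = full_split(m.data.shape[0])
        mt.assert_no_leakage(m, s)

    def test_group_spanning_splits_detected(self):
        m, _ = planted_matrix(n=10)
        assignment = {p: "train" for p in range(1, 11)}
        assignment[2] = "test"  # breaks the {1, 2} co-mutation group
        bad = mt.SplitAssignment(
            assignment=assignment, groups=(frozenset({1, 2}),), seed=0
        )
        with pytest.raises(AssertionError):
            mt.assert_no_leakage(m, bad)


class TestTrain:
    def test_planted_linear_recovery(self):
        m, noise = planted_matrix(seed=1)
        s = full_split(m.data.shape[0], seed=1)
        tm = mt.train(m, s, mt.TrainParams(seed=1))
        assert tm.best_val_rmse <= 2 * noise + 0.05
        assert tm.n_rounds <= 1000

    def test_constant_target_errors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        m = make_matrix(X, np.zeros(50))
        with pytest.raises(ValueError, match="degenerate"):
            mt.train(m, full_split(50), mt.TrainParams())

    def test_near_constant_early_stop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        y = 0.5 + rng.normal(0, 1e-6, size=80)
        m = make_matrix(X, y)
        tm = mt.train(m, full_split(80), mt.TrainParams(seed=0))
        assert tm.n_rounds < 100  # nothing to learn -> stops early

    def test_same_seed_identical_predictions(self):
        m, _ = planted_matrix(seed=3)
        s = full_split(m.data.shape[0], seed=3)
        a = mt.train(m, s, mt.TrainParams(seed=9))
        b = mt.train(m, s, mt.TrainParams(seed=9))
        np.testing.assert_array_equal(a.predict_rows(m), b.predict_rows(m))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            mt.TrainParams(patience=0)
        with pytest.raises(ValueError):
            mt.TrainParams(max_rounds=5, patience=10)
        with pytest.raises(ValueError):
            mt.TrainParams(objective="poisson")

    def test_binary_objective(self):
        m, _ = planted_matrix(seed=4)
        s = full_split(m.data.shape[0], seed=4)
        tm = mt.train(m, s, mt.TrainParams(seed=0, objective="binary"))
        p = tm.predict_rows(m)
        assert np.all((p >= 0) & (p <= 1))


class TestEvaluate:
    def test_perfect_predictions(self):
        obs = np.array([0.1, 0.4, 0.9, 0.3])
        rep = mt._metrics(obs, obs.copy(), np.array([0, 1, 1, 0], dtype=float))
        assert rep.r2 == 1.0 and rep.rmse == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([0.1, 0.4, 0.9, 0.3])
        pred = np.full(4, obs.mean())
        rep = mt._metrics(obs, pred, np.array([0, 1, 1, 0], dtype=float))
        assert rep.r2 == pytest.approx(0.0, abs=1e-12)

    def test_planted_signal_r2(self):
        m, _ = planted_matrix(seed=7)
        s = full_split(m.data.shape[0], seed=7)
        tm = mt.train(m, s, mt.TrainParams(seed=7))
        rep = mt.evaluate(tm, m, s)
        assert rep.r2 >= 0.8
        assert 0.0 <= rep.aupr <= 1.0 and 0.0 <= rep.auroc <= 1.0

    def test_variant_level_aggregation(self):
        # two rows of one variant are averaged before scoring
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        m = make_matrix(X, np.linspace(0.1, 0.6, 6))
        data = m.data.copy()
        data.loc[0, "variant_id"] = data.loc[1, "variant_id"]
        m2 = ft.FeatureMatrix(data=data, registry=m.registry)
        s = full_split(6)
        tm = mt.train(m2, s, mt.TrainParams(seed=0))
        preds = tm.predict_variants(m2)
        assert len(preds) == 5


class TestExplain:
    def test_single_feature_model_full_contribution(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = 1.5 * X[:, 0]
        m = make_matrix(X, y)
        s = full_split(200, seed=0)
        tm = mt.train(m, s, mt.TrainParams(seed=0))
        rep = mt.explain(tm, m, s)
        assert rep.percent["f0"] > 99.0
        assert rep.percent.sum() == pytest.approx(100.0)

    def test_additivity(self):
        m, _ = planted_matrix(seed=5)
        s = full_split(m.data.shape[0], seed=5)
        tm = mt.train(m, s, mt.TrainParams(seed=5))
        rep = mt.explain(tm, m, s)
        labels = np.array(mt.rows_to_splits(m, s))
        X = mt._design(m, tm.feature_names)[labels == "test"]
        preds = tm.model.predict(X)
        recon = rep.base_value + rep.values.sum(axis=1).to_numpy()
        np.testing.assert_allclose(recon, preds, atol=1e-6)

    def test_weight_order_recovered(self):
        m, _ = planted_matrix(seed=6)  # |w(f0)| > |w(f1)|, rest zero
        s = full_split(m.data.shape[0], seed=6)
        tm = mt.train(m, s, mt.TrainParams(seed=6))
        rep = mt.explain(tm, m, s)
        assert rep.mean_abs["f0"] > rep.mean_abs["f1"]
        assert list(rep.ranking[:2]) == ["f0", "f1"]

    def test_group_partition(self):
        m, _ = planted_matrix(seed=8)
        s = full_split(m.data.shape[0], seed=8)
        tm = mt.train(m, s, mt.TrainParams(seed=8))
        rep = mt.explain(tm, m, s)
        assert rep.group_percent.sum() == pytest.approx(100.0)

    def test_binary_objective_rejected(self):
        m, _ = planted_matrix(seed=4)
        s = full_split(m.data.shape[0], seed=4)
        tm = mt.train(m, s, mt.TrainParams(seed=0, objective="binary"))
        with pytest.raises(ValueError):
            mt.explain(tm, m, s)


class TestShapOracle:
    def test_single_tree_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 4))
        y = X[:, 0] * 2 + (X[:, 1] > 0) * X[:, 2]
        gbr = GradientBoostingRegressor(n_estimators=1, max_depth=3, random_state=0)
        gbr.fit(X, y)
        tree = gbr.estimators_[0, 0].tree_
        phi, _ = shp.single_tree_shapley(tree, X[:7])
        for r in range(7):
            ref = brute_shapley(tree, X[r])
            np.testing.assert_allclose(phi[r], ref, atol=1e-9)

    def test_expected_value_matches_leaf_paths(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 3))
        y = X[:, 0] - X[:, 2] ** 2
        gbr = GradientBoostingRegressor(n_estimators=1, max_depth=3, random_state=0)
        gbr.fit(X, y)
        tree = gbr.estimators_[0, 0].tree_
        for subset in [frozenset(), frozenset({0}), frozenset({0, 2})]:
            ours = shp.expected_value(tree, X[:5], subset)
            for r in range(5):
                ref = leaf_path_expectation(tree, X[r], subset)
                assert abs(ours[r] - ref) < 1e-9

    def test_full_model_additivity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 5))
        y = X[:, 0] + 0.5 * X[:, 3] * X[:, 4]
        gbr = GradientBoostingRegressor(n_estimators=40, random_state=0)
        gbr.fit(X, y)
        phi, base = shp.tree_shapley_values(gbr, X[:20])
        np.testing.assert_allclose(
            base + phi.sum(axis=1), gbr.predict(X[:20]), atol=1e-6
        )


class TestCrossSubstrate:
    def test_sanity_train_test_same(self):
        m, _ = planted_matrix(seed=9)
        s = full_split(m.data.shape[0], seed=9)
        tm = mt.train(m, s, mt.TrainParams(seed=9))
        within = mt.evaluate(tm, m, s)
        labels = np.array(mt.rows_to_splits(m, s))
        test_rows = m.data[labels == "test"]
        sub = ft.FeatureMatrix(data=test_rows, registry=m.registry)
        cross = mt.cross_substrate_eval(tm, sub)
        assert cross.r2 == pytest.approx(within.r2, abs=1e-9)

    def test_different_rule_drops(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 4))
        y1 = 0.7 * X[:, 0]
        m1 = make_matrix(X, y1)
        s = full_split(300, seed=10)
        tm = mt.train(m1, s, mt.TrainParams(seed=10))
        X2 = rng.normal(size=(200, 4))
        y2 = -0.7 * X2[:, 0]  # reversed rule
        m2 = make_matrix(X2, y2)
        within = mt.evaluate(tm, m1, s)
        cross = mt.cross_substrate_eval(tm, m2)
        assert within.r2 - cross.r2 >= 0.3

    def test_identical_rule_control(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 4))
        y1 = 0.7 * X[:, 0]
        m1 = make_matrix(X, y1)
        s = full_split(300, seed=11)
        tm = mt.train(m1, s, mt.TrainParams(seed=11))
        X2 = rng.normal(size=(200, 4))
        m2 = make_matrix(X2, 0.7 * X2[:, 0])
        within = mt.evaluate(tm, m1, s)
        cross = mt.cross_substrate_eval(tm, m2)
        assert abs(within.r2 - cross.r2) < 0.15

    def test_no_shared_features_errors(self):
        m, _ = planted_matrix(seed=12)
        s = full_split(m.data.shape[0], seed=12)
        tm = mt.train(m, s, mt.TrainParams(seed=12))
        rng = np.random.default_rng(0)
        other = make_matrix(rng.normal(size=(20, 2)), rng.uniform(size=20), names=["x1", "x2"])
        with pytest.raises(ValueError, match="shared"):
            mt.cross_substrate_eval(tm, other)
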