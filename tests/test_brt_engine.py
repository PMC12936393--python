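"""Boosted-tree engine: fitting, constraints, interpretation, CV machinery."""

import numpy as np
import pandas as pd
import pytest

import turtlehab as th
from turtlehab import brt_engine as be
from turtlehab.env_annotate import AnnotatedTable
from conftest import make_logistic_table, make_separable_table

FAST = th.BrtConfig(learning_rate=0.1, max_trees=100, seed=0)


class TestFit:
    def test_separable_truth_dominant_influence_and_auc(self):
        table = make_separable_table(n=5000, p=5, seed=1)
        hold = make_separable_table(n=2000, p=5, seed=2)
        cfg = th.BrtConfig(learning_rate=0.1, max_trees=200, seed=0)
        m = th.fit(table, cfg)
        infl = th.relative_influence(m)
        assert infl["x0"] > 90.0
        scores = th.predict(m, hold.data)
        assert th.auc(hold.data["label"], scores) > 0.99

    def test_same_seed_bit_identical(self):
        table = make_separable_table(n=800, p=4, seed=3)
        m1 = th.fit(table, FAST)
        m2 = th.fit(table, FAST)
        assert m1.to_json() == m2.to_json()
        x = table.data
        np.testing.assert_array_equal(th.predict(m1, x), th.predict(m2, x))

    def test_single_class_rejected(self):
        table = make_separable_table(n=100, p=3, seed=4)
        table.data["label"] = 1.0
        with pytest.raises(ValueError):
            th.fit(table, FAST)

    def test_training_bag_deviance_never_increases(self):
        table = make_logistic_table(n=2000, seed=5)[0]
        m = th.fit(table, th.BrtConfig(learning_rate=0.05, max_trees=200, seed=1))
        assert (m.bag_improvement >= -1e-9).all()

    def test_zero_learning_rate_limit_is_intercept(self):
        table = make_separable_table(n=500, p=3, seed=6)
        m = th.fit(table, FAST)
        p0 = th.predict(m, table.data, n_trees=0)
        np.testing.assert_allclose(p0, table.data["label"].mean(), atol=1e-12)


class TestMonotone:
    def test_constrained_pd_non_decreasing(self):
        table = make_logistic_table(n=3000, seed=7, beta=(1.5, -1.0))[0]
        cfg = th.BrtConfig(learning_rate=0.1, max_trees=150, seed=2,
                           monotone={"x0": 1, "x1": -1})
        m = th.fit(table, cfg)
        grid = np.linspace(table.data["x0"].min(), table.data["x0"].max(), 100)
        pd_curve = th.partial_dependence(m, "x0", grid, table.data)
        assert (np.diff(pd_curve) >= -1e-12).all()
        grid1 = np.linspace(table.data["x1"].min(), table.data["x1"].max(), 100)
        pd_curve1 = th.partial_dependence(m, "x1", grid1, table.data)
        assert (np.diff(pd_curve1) <= 1e-12).all()

    def test_monotone_probabilities_in_single_row(self):
        table = make_logistic_table(n=2000, seed=8)[0]
        cfg = th.BrtConfig(learning_rate=0.1, max_trees=100, seed=3,
                           monotone={"x0": 1})
        m = th.fit(table, cfg)
        row = table.data.iloc[[0]][m.feature_names].copy()
        probs = []
        for v in np.linspace(-3, 3, 50):
            r = row.copy()
            r["x0"] = v
            probs.append(th.predict(m, r)[0])
        assert (np.diff(probs) >= -1e-12).all()


class TestPredict:
    def test_intercept_only(self):
        table = make_separable_table(n=300, p=3, seed=9)
        m = th.fit(table, FAST)
        np.testing.assert_allclose(th.predict(m, table.data, n_trees=0),
                                   table.data["label"].mean())

    def test_single_vs_batched_rows_agree(self):
        table = make_separable_table(n=300, p=3, seed=10)
        m = th.fit(table, FAST)
        X = table.data[m.feature_names]
        batched = th.predict(m, X)
        single = np.array([th.predict(m, X.iloc[[i]])[0] for i in range(20)])
        np.testing.assert_allclose(batched[:20], single, atol=1e-9)

    def test_probabilities_strictly_inside_unit_interval(self):
        table = make_separable_table(n=300, p=3, seed=11)
        m = th.fit(table, FAST)
        p = th.predict(m, table.data)
        assert ((p > 0) & (p < 1)).all()


class TestInfluence:
    def test_sums_to_100(self):
        table = make_logistic_table(n=1500, seed=12)[0]
        m = th.fit(table, FAST)
        assert th.relative_influence(m).sum() == pytest.approx(100.0, abs=1e-6)

    def test_pure_noise_influence_spread(self):
        """Labels independent of 5 noise predictors: no predictor dominates
        (max influence < 40 over 10 seeds)."""
        maxima = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({f"x{i}": rng.standard_normal(5000) for i in range(5)})
            df["label"] = rng.integers(0, 2, 5000).astype(float)
            table = AnnotatedTable(df, [f"x{i}" for i in range(5)])
            m = th.fit(table, th.BrtConfig(learning_rate=0.1, max_trees=60,
                                           seed=seed))
            maxima.append(th.relative_influence(m).max())
        assert max(maxima) < 40.0

    def test_influential_flag_threshold(self):
        table = make_separable_table(n=2000, p=5, seed=13)
        m = th.fit(table, FAST)
        flagged = be.influential_predictors(m)
        infl = th.relative_influence(m)
        for p in m.feature_names:
            assert (p in flagged) == (infl[p] > 100.0 / 5)


class TestPartialDependence:
    def test_step_function_single_split(self):
        table = make_separable_table(n=2000, p=2, seed=14)
        cfg = th.BrtConfig(tree_complexity=1, learning_rate=0.5, max_trees=1,
                           bag_fraction=1.0, seed=0)
        m = th.fit(table, cfg)
        grid = np.array([-2.0, -0.5, 0.5, 2.0])
        curve = th.partial_dependence(m, "x0", grid, table.data)
        assert curve[0] == curve[1] < curve[2] == curve[3]

    def test_unused_predictor_constant(self):
        table = make_separable_table(n=1000, p=3, seed=15)
        cfg = th.BrtConfig(tree_complexity=1, learning_rate=0.3, max_trees=1,
                           bag_fraction=1.0, seed=0)
        m = th.fit(table, cfg)  # one stump, splitting on the separable x0
        assert not any(be._tree_uses(t, 2) for t in m.trees)
        curve = th.partial_dependence(m, "x2", np.linspace(-2, 2, 10), table.data)
        assert np.ptp(curve) < 1e-12

    def test_fast_path_equals_literal_brute_force(self):
        """Shortcut PD equals a literal per-grid-value override loop on a
        50-row, 20-tree model (<= 1e-9)."""
        table = make_logistic_table(n=50, seed=16)[0]
        cfg = th.BrtConfig(learning_rate=0.2, max_trees=20, seed=1)
        m = th.fit(table, cfg)
        grid = np.linspace(-2, 2, 15)
        fast = th.partial_dependence(m, "x0", grid, table.data)
        brute = []
        for g in grid:
            rows = table.data[m.feature_names].copy()
            rows["x0"] = g
            brute.append(be.decision_function(m, rows).mean())
        np.testing.assert_allclose(fast, np.asarray(brute), atol=1e-9)


class TestInteractions:
    def test_additive_truth_scores_low(self):
        """No-interaction ground truth: interaction score < 0.05 (10 seeds)."""
        for seed in range(10):
            table = make_logistic_table(n=4000, seed=20 + seed)[0]
            m = th.fit(table, th.BrtConfig(learning_rate=0.1, max_trees=80,
                                           seed=seed))
            s = th.interaction_strength(m, ("x0", "x1"), table.data)
            assert s < 0.05

    def test_xor_interaction_ranks_first(self):
        rng = np.random.default_rng(30)
        n = 6000
        df = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(3)})
        df["label"] = ((df["x0"] > 0) ^ (df["x1"] > 0)).astype(float)
        table = AnnotatedTable(df, ["x0", "x1", "x2"])
        m = th.fit(table, th.BrtConfig(learning_rate=0.1, max_trees=150,
                                       tree_complexity=3, seed=0))
        ranked = be.rank_interactions(m, table.data, top=3)
        top = {ranked.iloc[0]["predictor_a"], ranked.iloc[0]["predictor_b"]}
        assert top == {"x0", "x1"}

    def test_symmetry(self):
        table = make_logistic_table(n=1000, seed=31)[0]
        m = th.fit(table, FAST)
        a = th.interaction_strength(m, ("x0", "x1"), table.data)
        b = th.interaction_strength(m, ("x1", "x0"), table.data)
        assert a == pytest.approx(b, abs=1e-12)


class TestCrossValidation:
    def test_fold_sizes_balanced(self):
        table = make_separable_table(n=1000, p=3, seed=32)
        cv = th.cross_validate(table, th.BrtConfig(learning_rate=0.2,
                                                   max_trees=20, seed=0))
        sizes = np.bincount(cv.fold_assignment)
        assert len(sizes) == 5
        assert sizes.min() >= 199 and sizes.max() <= 201

    def test_mean_metrics_equal_mean_of_folds(self):
        table = make_separable_table(n=600, p=3, seed=33)
        cv = th.cross_validate(table, th.BrtConfig(learning_rate=0.2,
                                                   max_trees=20, seed=0))
        assert cv.mean_metrics["auc"] == pytest.approx(
            np.mean([m.auc for m in cv.fold_metrics]))

    def test_separable_truth_high_heldout_auc(self):
        table = make_separable_table(n=2000, p=5, seed=34)
        cv = th.cross_validate(table, th.BrtConfig(learning_rate=0.1,
                                                   max_trees=100, seed=0))
        assert cv.mean_metrics["auc"] > 0.95


class TestPruning:
    def _cv_with_influence(self, infl_rows, predictors):
        cv = be.CvResult(fold_models=[], fold_metrics=[],
                         fold_influence=pd.DataFrame(infl_rows,
                                                     columns=predictors),
                         fold_assignment=np.array([]), config=FAST,
                         predictors=predictors)
        return cv

    def test_zero_influence_everywhere_dropped(self):
        preds = [f"x{i}" for i in range(20)]
        rows = []
        for _ in range(5):
            r = np.linspace(1, 20, 20)
            r[0] = 0.0
            rows.append(100 * r / r.sum())
        cv = self._cv_with_influence(rows, preds)
        keep = th.prune_predictors(cv)
        assert "x0" not in keep

    def test_low_in_four_of_five_folds_retained(self):
        preds = [f"x{i}" for i in range(20)]
        rows = []
        for k in range(5):
            r = np.linspace(1, 20, 20)
            r[0] = 0.0 if k < 4 else 15.0  # escapes the bottom 10% once
            rows.append(100 * r / r.sum())
        cv = self._cv_with_influence(rows, preds)
        keep = th.prune_predictors(cv)
        assert "x0" in keep

    def test_noise_predictors_pruned_informative_survive(self):
        """Separable truth plus noise columns: the informative predictor
        survives and at least half the pure-noise columns are pruned."""
        survived_truth = 0
        for seed in range(10):
            table = make_separable_table(n=1500, p=8, seed=40 + seed)
            cv = th.cross_validate(table, th.BrtConfig(learning_rate=0.2,
                                                       max_trees=40, seed=seed))
            keep = th.prune_predictors(cv)
            if "x0" in keep:
                survived_truth += 1
        assert survived_truth >= 9

    def test_never_empties_list(self):
        preds = ["x0", "x1"]
        rows = [[50.0, 50.0]] * 5
        cv = self._cv_with_influence(rows, preds)
        with pytest.warns(UserWarning, match="every predictor"):
            keep = th.prune_predictors(cv)
        assert keep == preds


class TestOobSelection:
    def _cv_with_oob(self, curves):
        models = []
        for c in curves:
            m = be.BrtModel(trees=[], intercept=0.0, feature_names=[],
                            categorical=frozenset(), config=FAST,
                            oob_improvement=np.asarray(c, dtype=float),
                            train_deviance=np.array([]),
                            bag_improvement=np.array([]), y_mean=0.5)
            models.append(m)
        return be.CvResult(fold_models=models, fold_metrics=[],
                           fold_influence=pd.DataFrame(), fold_assignment=np.array([]),
                           config=FAST, predictors=[])

    def test_always_positive_improvement_uses_all_trees(self):
        cv = self._cv_with_oob([np.ones(300)] * 3)
        assert th.select_n_trees_oob(cv) == 300

    def test_negative_after_k_stops_near_k(self):
        k = 150
        curve = np.concatenate([np.ones(k), -np.ones(150)])
        cv = self._cv_with_oob([curve] * 3)
        chosen = th.select_n_trees_oob(cv, window=50)
        assert abs(chosen - k) <= 25  # within half the smoothing window

    def test_encompasses_every_fold(self):
        curves = [np.concatenate([np.ones(k), -np.ones(300 - k)])
                  for k in (80, 150, 220)]
        cv = self._cv_with_oob(curves)
        chosen = th.select_n_trees_oob(cv, window=1)
        assert chosen == 220


class TestCategorical:
    def test_exhaustive_subset_split_recovers_grouping(self):
        rng = np.random.default_rng(60)
        n = 4000
        codes = rng.integers(0, 6, size=n).astype(float)
        y = np.isin(codes, [1.0, 4.0]).astype(float)
        noise = rng.standard_normal(n)
        df = pd.DataFrame({"hab": codes, "x": noise, "label": y})
        table = AnnotatedTable(df, ["hab", "x"], categorical=frozenset({"hab"}))
        m = th.fit(table, th.BrtConfig(learning_rate=0.3, max_trees=30, seed=0))
        p = th.predict(m, table.data)
        assert th.auc(y, p) > 0.99

    def test_unseen_code_routes_majority_and_warns_nothing_fatal(self):
        rng = np.random.default_rng(61)
        n = 1000
        codes = rng.integers(0, 4, size=n).astype(float)
        df = pd.DataFrame({"hab": codes,
                           "x": rng.standard_normal(n),
                           "label": np.isin(codes, [1.0]).astype(float)})
        table = AnnotatedTable(df, ["hab", "x"], categorical=frozenset({"hab"}))
        m = th.fit(table, th.BrtConfig(learning_rate=0.3, max_trees=20, seed=0))
        row = pd.DataFrame({"hab": [99.0], "x": [0.0]})
        p = th.predict(m, row)
        assert 0.0 < p[0] < 1.0
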