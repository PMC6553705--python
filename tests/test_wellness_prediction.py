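import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

from netwell.behavior_features import BEHAVIOR_FEATURES
from netwell.correlation_analysis import STRUCTURE_COLUMNS
from netwell.wellness_prediction import (
    CLASSIFIER_ORDER,
    PARAM_GRIDS,
    RF_DEFAULT_TREES,
    TunedClassifier,
    assemble_dataset,
    ensemble_vote,
    enumerate_weight_grid,
    expected_random_f1,
    f1_report,
    optimize_weights,
    random_baseline,
    relative_improvement,
    run_prediction,
    select_top3,
    simplex_grid,
    split_train_test,
    tune_base_classifiers,
)

CLASSES4 = np.arange(1, 5)


def _feature_table(rng, n_participants=30, n_weeks=6):
    rows = []
    for p in range(n_participants):
        gender = "male" if p % 2 else "female"
        label = 1 + (p % 4)
        for w in range(n_weeks):
            row = {"participant": f"P{p}", "week": w, "gender": gender,
                   "stress": label, "happiness": label, "positive_attitude": label,
                   "health": label}
            for col in (*BEHAVIOR_FEATURES, *STRUCTURE_COLUMNS):
                row[col] = rng.normal(loc=label, scale=1.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestAssemble:
    def test_network_only_has_ten_feature_columns(self):
        df = assemble_dataset(_feature_table(np.random.default_rng(0)), "stress", "network_only")
        features = df.drop(columns=["participant", "week", "label"])
        assert features.shape[1] == 10

    def test_baseline_has_thirteen_feature_columns(self):
        df = assemble_dataset(_feature_table(np.random.default_rng(0)), "stress", "baseline")
        assert df.drop(columns=["participant", "week", "label"]).shape[1] == 13

    def test_full_has_twentythree_feature_columns(self):
        df = assemble_dataset(_feature_table(np.random.default_rng(0)), "stress", "full")
        assert df.drop(columns=["participant", "week", "label"]).shape[1] == 23

    def test_missing_label_rows_excluded(self):
        table = _feature_table(np.random.default_rng(1))
        table.loc[table.participant == "P0", "stress"] = np.nan
        df = assemble_dataset(table, "stress", "full")
        assert "P0" not in set(df.participant)

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError):
            assemble_dataset(_feature_table(np.random.default_rng(2)), "stress", "everything")


class TestSplit:
    def test_participant_unit_has_no_leakage(self):
        df = assemble_dataset(_feature_table(np.random.default_rng(3)), "stress", "full")
        train, test = split_train_test(df, seed=0)
        assert set(train.participant).isdisjoint(test.participant)
        assert len(train) + len(test) == len(df)

    def test_row_unit_floor_rule(self):
        df = assemble_dataset(
            _feature_table(np.random.default_rng(4), n_participants=20, n_weeks=5),
            "stress", "full",
        )  # 100 rows
        train, test = split_train_test(df, frac=0.75, unit="row", seed=0)
        assert len(train) == 75

    def test_full_fraction_rejected(self):
        df = assemble_dataset(_feature_table(np.random.default_rng(5)), "stress", "full")
        with pytest.raises(ValueError):
            split_train_test(df, frac=1.0)

    def test_deterministic_per_seed(self):
        df = assemble_dataset(_feature_table(np.random.default_rng(6)), "stress", "full")
        t1, _ = split_train_test(df, seed=42)
        t2, _ = split_train_test(df, seed=42)
        pd.testing.assert_frame_equal(t1, t2)


class TestWeightGrid:
    def test_scalar_grid_has_66_matrices(self):
        grid = enumerate_weight_grid("scalar", n_classes=4)
        assert grid.shape == (66, 3, 4)
        assert np.allclose(grid[:, :, 0].sum(axis=1), 1.0)

    def test_per_class_simplex_has_286_rows_at_k4(self):
        assert simplex_grid(4, 0.1).shape == (286, 4)

    def test_step_one_scalar_gives_three_one_hots(self):
        grid = enumerate_weight_grid("scalar", n_classes=4, step=1.0)
        assert grid.shape[0] == 3
        assert sorted(tuple(g[:, 0]) for g in grid) == [
            (0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0)
        ]

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            simplex_grid(3, 0.3)
        with pytest.raises(ValueError):
            simplex_grid(3, 1.5)

    def test_per_class_rows_live_on_simplex(self):
        rows = simplex_grid(4, 0.1)
        assert np.allclose(rows.sum(axis=1), 1.0)
        assert (rows >= 0).all()


class TestEnsembleVote:
    def test_one_hot_weights_reduce_to_single_classifier(self):
        rng = np.random.default_rng(7)
        P = rng.dirichlet(np.ones(4), size=(50, 3)).reshape(50, 3, 4)
        for i in range(3):
            W = np.zeros((3, 4))
            W[i] = 1.0
            votes = ensemble_vote(P, W, CLASSES4)
            assert np.array_equal(votes, CLASSES4[np.argmax(P[:, i, :], axis=1)])

    def test_uniform_weight_example(self):
        P = np.array([[[0.5, 0.2, 0.2, 0.1],
                       [0.1, 0.6, 0.2, 0.1],
                       [0.3, 0.3, 0.3, 0.1]]])
        W = np.full((3, 4), 1.0)
        assert ensemble_vote(P, W, CLASSES4)[0] == 2  # column sums (.9, 1.1, .7, .3)

    def test_exact_tie_breaks_to_lower_class(self):
        P = np.array([[[0.4, 0.4, 0.1, 0.1],
                       [0.4, 0.4, 0.1, 0.1],
                       [0.4, 0.4, 0.1, 0.1]]])
        W = np.full((3, 4), 1 / 3)
        assert ensemble_vote(P, W, CLASSES4)[0] == 1

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            ensemble_vote(np.zeros((5, 3, 4)), np.zeros((3, 5)), CLASSES4)


def _fold(P, y):
    return [(P, y)]


class TestOptimizeWeights:
    def test_grid_of_size_one_returned(self):
        rng = np.random.default_rng(8)
        P = rng.dirichlet(np.ones(4), size=(20, 3)).reshape(20, 3, 4)
        y = rng.integers(1, 5, 20)
        W = optimize_weights(_fold(P, y), CLASSES4, mode="scalar", step=1.0)
        assert W.shape == (3, 4)

    def test_identical_classifiers_return_first_grid_point(self):
        rng = np.random.default_rng(9)
        base = rng.dirichlet(np.ones(4), size=20)
        P = np.repeat(base[:, None, :], 3, axis=1)
        y = rng.integers(1, 5, 20)
        W = optimize_weights(_fold(P, y), CLASSES4, mode="scalar")
        first = enumerate_weight_grid("scalar", n_classes=4)[0]
        assert np.allclose(W, first)

    def test_perfect_classifier_dominates(self):
        rng = np.random.default_rng(10)
        n = 120
        y = rng.integers(1, 5, n)
        perfect = np.eye(4)[y - 1] * 0.97 + 0.01
        noise1 = rng.dirichlet(np.ones(4), size=n)
        noise2 = rng.dirichlet(np.ones(4), size=n)
        P = np.stack([noise1, perfect, noise2], axis=1)
        W = optimize_weights(_fold(P, y), CLASSES4, mode="scalar")
        assert W[1, 0] >= 0.5

    def test_never_below_best_single_classifier(self):
        from netwell.wellness_prediction import _macro_f1

        rng = np.random.default_rng(11)
        for trial in range(5):
            P = rng.dirichlet(np.ones(4), size=(60, 3)).reshape(60, 3, 4)
            y = rng.integers(1, 5, 60)
            folds = _fold(P, y)
            W = optimize_weights(folds, CLASSES4, mode="scalar")
            best_single = max(
                _macro_f1(y, CLASSES4[np.argmax(P[:, i, :], axis=1)], CLASSES4)
                for i in range(3)
            )
            achieved = _macro_f1(y, ensemble_vote(P, W, CLASSES4), CLASSES4)
            assert achieved >= best_single - 1e-12

    def test_per_class_coordinate_ascent_improves_on_uniform(self):
        from netwell.wellness_prediction import _macro_f1

        rng = np.random.default_rng(12)
        P = rng.dirichlet(np.ones(4), size=(80, 3)).reshape(80, 3, 4)
        y = rng.integers(1, 5, 80)
        folds = _fold(P, y)
        W = optimize_weights(folds, CLASSES4, mode="per_class")
        uniform = np.full((3, 4), 0.25)
        assert _macro_f1(y, ensemble_vote(P, W, CLASSES4), CLASSES4) >= _macro_f1(
            y, ensemble_vote(P, uniform, CLASSES4), CLASSES4
        )
        assert np.allclose(W.sum(axis=1), 1.0)  # rows stay on the simplex


class TestSelection:
    def _tuned(self, scores):
        return {
            name: TunedClassifier(name, None, score, {})
            for name, score in scores.items()
        }

    def test_top_three_by_cv_accuracy(self):
        scores = {"SVM": 0.60, "KNN": 0.55, "RF": 0.58, "LR": 0.50, "CART": 0.45}
        assert set(select_top3(self._tuned(scores))) == {"SVM", "RF", "KNN"}
        assert select_top3(self._tuned(scores)) == ["SVM", "RF", "KNN"]

    def test_all_equal_scores_use_fixed_order(self):
        scores = {name: 0.5 for name in CLASSIFIER_ORDER}
        assert select_top3(self._tuned(scores)) == ["KNN", "CART", "SVM"]

    def test_rf_grid_has_19_tree_counts(self):
        assert len(PARAM_GRIDS["full"]["RF"][0]["clf__n_estimators"]) == 19

    def test_rf_default_is_35_trees(self):
        assert RF_DEFAULT_TREES == 35


class TestF1:
    def test_perfect_predictions(self):
        r = f1_report([1, 2, 3, 4], [1, 2, 3, 4], K=4)
        assert r.overall == 1.0 and all(v == 1.0 for v in r.per_level.values())

    def test_hand_confusion_example(self):
        r = f1_report([1, 1, 2, 2], [1, 2, 2, 2], K=2)
        assert r.per_level[1] == pytest.approx(2 / 3, abs=5e-4)
        assert r.per_level[2] == pytest.approx(0.8)
        assert r.overall == pytest.approx(0.733, abs=5e-4)

    def test_absent_class_zero_rule(self):
        r = f1_report([1, 1], [1, 1], K=4)
        assert r.per_level[3] == 0.0

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            y_true = rng.integers(1, 5, 100)
            y_pred = rng.integers(1, 5, 100)
            r = f1_report(y_true, y_pred, K=4)
            expected = f1_score(y_true, y_pred, labels=CLASSES4, average="macro",
                                zero_division=0)
            assert r.overall == pytest.approx(expected, abs=1e-12)


class TestRandomBaseline:
    def test_balanced_closed_form(self):
        assert expected_random_f1(0.25, 4) == pytest.approx(0.25)

    def test_rare_class_closed_form(self):
        assert expected_random_f1(0.0431, 4) == pytest.approx(0.0735, abs=5e-4)

    def test_simulation_reproducible(self):
        y = np.repeat(CLASSES4, 25)
        d1, r1 = random_baseline(y, 4, seed=3, reps=10)
        d2, r2 = random_baseline(y, 4, seed=3, reps=10)
        assert np.array_equal(d1, d2) and r1.overall == r2.overall

    def test_simulation_near_closed_form_for_balanced_classes(self):
        y = np.repeat(CLASSES4, 250)
        _, report = random_baseline(y, 4, seed=5, reps=400)
        for c in CLASSES4:
            assert report.per_level[int(c)] == pytest.approx(0.25, abs=0.01)


class TestImprovement:
    @pytest.mark.parametrize(
        "base, full, expected",
        [
            (0.42, 0.58, 38),
            (0.31, 0.51, 65),
            (0.31, 0.48, 55),
            (0.35, 0.54, 54),
            (0.06, 0.43, 617),
            (0.13, 0.37, 185),
            (0.13, 0.39, 200),
            (0.22, 0.44, 100),
            (0.34, 0.55, 62),
            (0.24, 0.44, 83),
        ],
    )
    def test_reference_improvement_pairs(self, base, full, expected):
        assert relative_improvement(base, full) == expected

    def test_no_change_is_zero(self):
        assert relative_improvement(0.37, 0.37) == 0

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            relative_improvement(0.0, 0.5)

    def test_half_rounds_away_from_zero(self):
        assert relative_improvement(0.40, 0.41) == 3  # 2.5 -> 3
        assert relative_improvement(0.40, 0.39) == -3


class TestEndToEnd:
    def test_tuning_reproducible_and_informative(self):
        table = _feature_table(np.random.default_rng(14), n_participants=24, n_weeks=4)
        df = assemble_dataset(table, "stress", "full")
        train, test = split_train_test(df, seed=1)
        t1 = tune_base_classifiers(train, grid="none", seed=1)
        t2 = tune_base_classifiers(train, grid="none", seed=1)
        assert {k: v.cv_accuracy for k, v in t1.items()} == {
            k: v.cv_accuracy for k, v in t2.items()
        }
        # label depends strongly on the features, so CV accuracy beats chance
        assert max(v.cv_accuracy for v in t1.values()) > 0.4

    def test_run_prediction_learns_planted_signal(self):
        table = _feature_table(np.random.default_rng(15), n_participants=32, n_weeks=5)
        res = run_prediction(table, "stress", "full", seed=2, grid="none")
        assert res.report.overall > 0.5  # labels are a clean function of features
        assert len(res.model.classifiers) == 3
        assert np.allclose(res.model.weights[:, 0].sum(), 1.0)
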