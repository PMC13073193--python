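"""Classifier training protocol, resampling, and DeLong AUC inference."""

import numpy as np
import pytest

from t1dprs import (
    NetworkConfig,
    TrainConfig,
    auc,
    auc_with_delong_ci,
    fit,
    grid_search_cv,
    load_model,
    save_model,
    split_train_test,
    undersample,
)

from conftest import make_subjects

SMALL_NET = NetworkConfig(hidden_sizes=(16, 8, 4), dropout_rates=(0.2, 0.1, 0.0), seed=0)


def separable_data(n, seed=0, gap=3.0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, 5))
    X[:, 0] += gap * y
    return X, y


class TestUndersample:
    def test_ratio_counts(self):
        subjects = make_subjects(546, 11363)
        sel = undersample(subjects, "1:3", seed=0)
        assert sum(l == "case" for l in sel.labels) == 546
        assert sum(l == "control" for l in sel.labels) == 3 * 546

    def test_all_is_identity(self):
        subjects = make_subjects(10, 50)
        assert undersample(subjects, "all", seed=0) is subjects

    def test_nested_control_subsets(self):
        subjects = make_subjects(20, 200)
        sets = {}
        for ratio in ("1:1", "1:2", "1:3"):
            sel = undersample(subjects, ratio, seed=7)
            sets[ratio] = {s for s, l in zip(sel.subject_ids, sel.labels) if l == "control"}
        assert sets["1:1"] < sets["1:2"] < sets["1:3"]

    def test_insufficient_controls_reports_max(self):
        subjects = make_subjects(100, 150)
        with pytest.raises(ValueError, match="1:1"):
            undersample(subjects, "1:2", seed=0)


class TestSplitTrainTest:
    def test_sizes_and_ratio(self):
        subjects = make_subjects(546, 11363)
        train, test = split_train_test(subjects, seed=0)
        n_test = int(round(0.2 * 11909))
        assert len(test) == n_test
        cases = test.y.sum()
        assert cases == int(round(n_test / 10))  # 1:9 case:control
        assert len(train) + len(test) == 11909

    def test_disjoint_and_deterministic(self):
        subjects = make_subjects(100, 900)
        tr1, te1 = split_train_test(subjects, seed=3)
        tr2, te2 = split_train_test(subjects, seed=3)
        assert set(tr1.subject_ids) & set(te1.subject_ids) == set()
        assert tr1.subject_ids == tr2.subject_ids and te1.subject_ids == te2.subject_ids

    def test_aux_controls_never_in_training(self):
        subjects = make_subjects(50, 450, n_aux=30)
        train, test = split_train_test(subjects, seed=1)
        assert "aux_control" not in train.labels
        assert sum(l == "aux_control" for l in test.labels) == 30

    def test_unattainable_split_errors(self):
        subjects = make_subjects(5, 5)  # too few controls for a 1:9 test set
        with pytest.raises(ValueError):
            split_train_test(subjects, test_fraction=0.8, seed=0)


class TestFitPredict:
    def test_predictions_strictly_inside_unit_interval(self):
        X, y = separable_data(100, seed=1)
        model = fit(X, y, net=SMALL_NET, train=TrainConfig(seed=1, max_epochs=20, patience=5))
        p = model.predict_proba(X)
        assert np.all((p > 0) & (p < 1))

    def test_same_seeds_identical_predictions(self):
        X, y = separable_data(80, seed=2)
        cfg = TrainConfig(seed=5, max_epochs=15, patience=5)
        p1 = fit(X, y, net=SMALL_NET, train=cfg).predict_proba(X)
        p2 = fit(X, y, net=SMALL_NET, train=cfg).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_memorizes_tiny_separable_set(self):
        # capacity check: 32 separable points, no dropout, enough epochs
        X, y = separable_data(32, seed=3, gap=4.0)
        net = NetworkConfig(hidden_sizes=(16, 8, 4), dropout_rates=(0.0, 0.0, 0.0), seed=0)
        cfg = TrainConfig(
            optimizer="adam", learning_rate=0.01, max_epochs=300, patience=300,
            validation_fraction=0.0, seed=0,
        )
        model = fit(X, y, net=net, train=cfg)
        assert np.mean((model.predict_proba(X) >= 0.5) == y) == 1.0

    def test_permuting_subjects_permutes_outputs(self):
        X, y = separable_data(60, seed=4)
        model = fit(X, y, net=SMALL_NET, train=TrainConfig(seed=1, max_epochs=10, patience=3))
        perm = np.random.default_rng(0).permutation(60)
        assert np.allclose(model.predict_proba(X)[perm], model.predict_proba(X[perm]))

    def test_zero_weight_model_outputs_half(self):
        X, y = separable_data(40, seed=5)
        model = fit(X, y, net=SMALL_NET, train=TrainConfig(seed=1, max_epochs=2, patience=2))
        for l in range(len(model.mlp.W)):
            model.mlp.W[l][:] = 0
            model.mlp.b[l][:] = 0
        assert np.allclose(model.predict_proba(X), 0.5)

    def test_extreme_inputs_finite(self, panel):
        X, y = separable_data(50, seed=6)
        model = fit(X, y, net=SMALL_NET, train=TrainConfig(seed=1, max_epochs=5, patience=3))
        p = model.predict_proba(np.full((3, 5), 2.0))
        assert np.all(np.isfinite(p))

    def test_width_mismatch_rejected(self):
        X, y = separable_data(40, seed=7)
        model = fit(X, y, net=SMALL_NET, train=TrainConfig(seed=1, max_epochs=2, patience=2))
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(np.zeros((2, 9)))

    def test_entropy_columns_standardized(self):
        from t1dprs.panel import FeatureMatrix

        rng = np.random.default_rng(8)
        X = np.column_stack([rng.integers(0, 3, size=(50, 3)), 30 + rng.normal(0, 5, 50)])
        y = (X[:, 3] > 30).astype(int)
        fm = FeatureMatrix(X, ["rs1", "rs2", "rs3", "H_global"], "count", [f"s{i}" for i in range(50)])
        model = fit(fm, y, net=SMALL_NET, train=TrainConfig(seed=1, max_epochs=5, patience=3))
        assert model.scale_columns == [3]
        assert model.scale_mean == pytest.approx(X[:, 3].mean())

    def test_save_load_roundtrip(self, tmp_path):
        X, y = separable_data(60, seed=9)
        model = fit(X, y, net=SMALL_NET, train=TrainConfig(seed=2, max_epochs=10, patience=3))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.array_equal(model.predict_proba(X), back.predict_proba(X))


class TestGridSearch:
    def test_grid_cardinality_and_fold_count(self):
        X, y = separable_data(150, seed=10)
        cv = grid_search_cv(
            X, y, net=SMALL_NET,
            train=TrainConfig(seed=0, max_epochs=5, patience=2),
            optimizers=("sgd", "adam"), learning_rates=(0.1, 0.01, 0.001),
            seed=0,
        )
        assert len(cv.all_results) == 6
        assert len(cv.fold_aucs) == 5

    def test_separable_data_beats_logistic_oracle_floor(self):
        # lower-bound sanity: a linear model sets the bar the grid must clear
        from sklearn.linear_model import LogisticRegression

        X, y = separable_data(200, seed=11)
        lr_auc = auc(
            LogisticRegression().fit(X, y).decision_function(X), y
        )
        cv = grid_search_cv(
            X, y, net=SMALL_NET,
            train=TrainConfig(seed=0, max_epochs=40, patience=10),
            optimizers=("adam",), learning_rates=(0.01,), seed=0,
        )
        assert lr_auc > 0.95
        assert cv.mean_auc > 0.95

    def test_selection_ignores_everything_but_training_data(self):
        # interface-level: selection is a pure function of (features, labels, seeds)
        X, y = separable_data(120, seed=12)
        kwargs = dict(
            net=SMALL_NET, train=TrainConfig(seed=0, max_epochs=5, patience=2),
            optimizers=("sgd", "adam"), learning_rates=(0.1, 0.01), seed=0,
        )
        cv1 = grid_search_cv(X, y, **kwargs)
        cv2 = grid_search_cv(X.copy(), y.copy(), **kwargs)
        assert (cv1.best_optimizer, cv1.best_learning_rate) == (
            cv2.best_optimizer, cv2.best_learning_rate
        )
        assert cv1.mean_auc == cv2.mean_auc

    def test_single_class_data_rejected(self):
        X = np.zeros((20, 3))
        y = np.ones(20, dtype=int)
        with pytest.raises(ValueError):
            grid_search_cv(X, y, net=SMALL_NET, train=TrainConfig(max_epochs=2))


class TestAUC:
    def test_perfect_separation(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(13)
        scores = rng.integers(0, 10, size=150).astype(float)  # ties on purpose
        labels = rng.integers(0, 2, size=150)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(14)
        n = 2000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        est = auc_with_delong_ci(scores, labels)
        assert abs(est.auc - 0.5) < 3 * np.sqrt(est.variance)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_ci_brackets_auc_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(15)
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 70)])
        labels = np.array([1] * 30 + [0] * 70)
        est = auc_with_delong_ci(scores, labels)
        assert 0 <= est.ci_low <= est.auc <= est.ci_high <= 1

    def test_delong_variance_matches_bootstrap(self):
        # oracle: nonparametric bootstrap of subjects, 2000 replicates
        rng = np.random.default_rng(16)
        n = 200
        labels = np.array([1] * 60 + [0] * 140)
        scores = np.where(labels == 1, rng.normal(1.0, 1, n), rng.normal(0, 1, n))
        est = auc_with_delong_ci(scores, labels)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) < 2:
                continue
            boots.append(auc(scores[idx], labels[idx]))
        boot_var = np.var(boots, ddof=1)
        assert abs(est.variance - boot_var) / boot_var < 0.25

    def test_sklearn_agreement(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(0, 1, 300) > 0).astype(int)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))
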