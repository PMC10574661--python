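"""Model tuning protocol, DNN epoch selection and the experiment grid."""

import numpy as np
import pytest

import qsarscreen as qs
from qsarscreen.featurize import FeatureMatrix
from qsarscreen.models import DEFAULT_GRIDS, TopKSelector


def _planted_classification(n=120, d=12, seed=0):
    """Binary features where one column determines the class."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, d)) < 0.4).astype(float)
    y = X[:, 0].astype(int)
    # guarantee both classes
    y[0], X[0, 0] = 1, 1
    y[1], X[1, 0] = 0, 0
    return X, y


def _planted_regression(n=150, d=10, seed=1, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + noise * rng.normal(size=n)
    return X, y


class TestTuneAndTrain:
    def test_single_point_grid_equals_direct_fit(self):
        X, y = _planted_classification()
        grid = {"n_estimators": [50], "max_leaf_nodes": [32]}
        model = qs.tune_and_train("random_forest", X, y,
                                  task="classification", param_grid=grid,
                                  cv_repeats=1, random_state=0)
        assert model.best_params == {"n_estimators": 50, "max_leaf_nodes": 32}

    @pytest.mark.parametrize("algorithm", ["svm_rbf", "grad_boost"])
    def test_separable_data_reaches_perfect_mcc(self, algorithm):
        X, y = _planted_classification(seed=2)
        grid = {k: v[:2] for k, v in
                DEFAULT_GRIDS["classification"][algorithm].items()}
        model = qs.tune_and_train(algorithm, X[:80], y[:80],
                                  task="classification", param_grid=grid,
                                  cv_repeats=1, random_state=0)
        test_mcc = qs.mcc(qs.confusion(y[80:], model.predict(X[80:])))
        assert test_mcc == 1.0

    def test_same_seed_same_hyperparameters(self):
        X, y = _planted_regression()
        kw = dict(task="regression",
                  param_grid={"C": [1, 10], "gamma": [0.01, 0.1],
                              "epsilon": [0.1]},
                  cv_repeats=2, random_state=5)
        m1 = qs.tune_and_train("svm_rbf", X, y, **kw)
        m2 = qs.tune_and_train("svm_rbf", X, y, **kw)
        assert m1.best_params == m2.best_params

    def test_regression_descriptor_count_is_tuned(self):
        X, y = _planted_regression(n=200, d=20, seed=3)
        names = [f"f{i}" for i in range(20)]
        fm = FeatureMatrix(X, names, "descriptor")
        ranking = qs.rfrfe_rank(fm, y, seed=0, n_estimators=50)
        ranking_idx = [names.index(r) for r in ranking]
        reg = qs.QSARRegressor(
            algorithm="svm_rbf",
            param_grid={"C": [10], "gamma": [0.1], "epsilon": [0.1]},
            descriptor_ranking=ranking_idx, n_descriptors_grid=[2, 5, "all"],
            cv_repeats=1, random_state=0).fit(fm, y)
        assert reg.best_params_["topk__k"] in (2, 5, 20)
        assert qs.rmse(y, reg.predict(fm)) < 0.5

    def test_degenerate_labels_error(self):
        X = np.random.default_rng(0).random((20, 4))
        with pytest.raises(ValueError):
            qs.QSARClassifier(algorithm="svm_rbf",
                              param_grid={"C": [1], "gamma": [0.1]},
                              cv_repeats=1).fit(X, np.ones(20, dtype=int))

    def test_manifest_records_provenance(self, tmp_path):
        import json
        X, y = _planted_classification()
        model = qs.tune_and_train("random_forest", X, y,
                                  task="classification",
                                  param_grid={"n_estimators": [20]},
                                  cv_repeats=1, random_state=3)
        model.save_manifest(tmp_path / "m.json")
        manifest = json.loads((tmp_path / "m.json").read_text())
        assert manifest["algorithm"] == "random_forest"
        assert manifest["best_params"] == {"n_estimators": 20}
        assert manifest["n_features"] == 12

    def test_trained_model_enforces_feature_contract(self):
        X, y = _planted_classification()
        fm = FeatureMatrix(X, [f"b{i}" for i in range(12)], "fingerprint")
        model = qs.tune_and_train(
            "random_forest", fm, y, task="classification",
            param_grid={"n_estimators": [20]}, cv_repeats=1)
        other = FeatureMatrix(X, [f"x{i}" for i in range(12)], "fingerprint")
        with pytest.raises(ValueError, match="contract"):
            model.predict(other)


class TestTopKSelector:
    def test_selects_ranked_prefix(self):
        X = np.arange(12.0).reshape(3, 4)
        sel = TopKSelector(ranking=[2, 0, 3, 1], k=2).fit(X)
        assert np.array_equal(sel.transform(X), X[:, [2, 0]])

    def test_all_keeps_everything(self):
        X = np.arange(12.0).reshape(3, 4)
        assert TopKSelector(ranking=[3, 2, 1, 0], k="all").fit(
            X).transform(X).shape == (3, 4)


class TestDNN:
    _small = dict(hidden_layer_sizes=(64, 32, 16, 8), learning_rate=1e-3,
                  cv_folds=3, cv_repeats=1, batch_size=32)

    def test_separable_data_high_mcc(self):
        X, y = _planted_classification(n=200, seed=4)
        net = qs.DNNClassifier(max_epochs=300, patience=30,
                               random_state=0, **self._small)
        net.fit(X[:140], y[:140])
        assert qs.mcc(qs.confusion(y[140:], net.predict(X[140:]))) >= 0.9

    def test_epoch_choice_deterministic(self):
        X, y = _planted_classification(n=90, seed=5)
        nets = [qs.DNNClassifier(max_epochs=40, patience=5, random_state=7,
                                 **self._small).fit(X, y) for _ in range(2)]
        assert nets[0].n_epochs_ == nets[1].n_epochs_
        assert nets[0].stopped_epochs_ == nets[1].stopped_epochs_

    def test_immediate_patience_minimal_epochs(self):
        X, y = _planted_classification(n=60, seed=6)
        net = qs.DNNClassifier(max_epochs=100, patience=1, random_state=0,
                               **self._small).fit(X, y)
        # patience 1 stops as soon as the validation score fails to improve
        assert net.n_epochs_ <= 10

    def test_regression_converges(self):
        X, y = _planted_regression(n=150, seed=7)
        net = qs.DNNRegressor(max_epochs=300, patience=30, random_state=0,
                              **self._small).fit(X[:100], y[:100])
        assert qs.rmse(y[100:], net.predict(X[100:])) < 1.0


class TestExperimentGrid:
    def test_full_factorial_counts(self):
        jobs = qs.experiment_grid(["d1", "d2", "d4", "d5"],
                                  ["maccs166", "avalon1024", "ecfp4_1024"],
                                  ["svm_rbf", "random_forest", "grad_boost",
                                   "dnn"], n_repeats=10)
        assert len(jobs) == 480

    def test_regression_design_counts(self):
        jobs = qs.experiment_grid(["d3", "d6"],
                                  ["physchem_2d", "fragment_counts"],
                                  ["svm_rbf", "random_forest", "grad_boost",
                                   "dnn"], n_repeats=10)
        assert len(jobs) == 160

    def test_minimal_grid(self):
        jobs = qs.experiment_grid(["d"], ["f"], ["a"], n_repeats=1)
        assert jobs == [{"dataset": "d", "repeat": 0, "featurization": "f",
                         "algorithm": "a"}]

    def test_stable_ordering(self):
        a = qs.experiment_grid(["d1", "d2"], ["f1"], ["a1", "a2"], 2)
        b = qs.experiment_grid(["d1", "d2"], ["f1"], ["a1", "a2"], 2)
        assert a == b

    def test_empty_factor_errors(self):
        with pytest.raises(ValueError):
            qs.experiment_grid([], ["f"], ["a"], 1)
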