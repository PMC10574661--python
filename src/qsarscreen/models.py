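"""QSAR model families and the grid-search tuning protocol.

Four supervised families are supported for both classification (high vs
weak inhibition) and regression (pIC50): an RBF-kernel support vector
machine, a random forest, gradient-boosted trees (XGBoost) and a
feed-forward neural network with four hidden layers. Hyperparameters are
chosen by grid search under repeated 5-fold cross-validation — smallest
mean CV MSE for regression, largest mean CV MCC for classification — and
the winning settings are refit on the full training partition. For
regression the number of top-ranked descriptors (from RF-RFE) is itself a
grid dimension.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import make_scorer
from sklearn.model_selection import (GridSearchCV, RepeatedKFold,
                                     RepeatedStratifiedKFold, StratifiedKFold,
                                     KFold)
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from .featurize import FeatureMatrix
from .metrics import confusion, mcc, q_accuracy, r2, rmse

ALGORITHMS = ("svm_rbf", "random_forest", "grad_boost", "dnn")

#: Default hyperparameter grids (config-exposed; desk-scale choices).
DEFAULT_GRIDS = {
    "classification": {
        "svm_rbf": {"C": [0.1, 1, 10, 100], "gamma": [1e-3, 1e-2, 1e-1, 1.0]},
        "random_forest": {"n_estimators": [100, 300, 500],
                          "max_leaf_nodes": [32, 128, 512, None]},
        "grad_boost": {"n_estimators": [100, 300, 500],
                       "max_depth": [3, 6, 9],
                       "subsample": [0.6, 0.8, 1.0],
                       "colsample_bytree": [0.6, 0.8, 1.0]},
    },
    "regression": {
        "svm_rbf": {"C": [0.1, 1, 10, 100], "gamma": [1e-3, 1e-2, 1e-1, 1.0],
                    "epsilon": [0.01, 0.1, 0.2]},
        "random_forest": {"n_estimators": [100, 300, 500],
                          "max_leaf_nodes": [32, 128, 512, None]},
        "grad_boost": {"n_estimators": [100, 300, 500],
                       "max_depth": [3, 6, 9],
                       "subsample": [0.6, 0.8, 1.0],
                       "colsample_bytree": [0.6, 0.8, 1.0]},
    },
}

DEFAULT_N_DESCRIPTORS_GRID = [10, 20, 40, 80, "all"]


def _mcc_score(y_true, y_pred) -> float:
    return mcc(confusion(y_true, y_pred))


MCC_SCORER = make_scorer(_mcc_score)


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


def _base_estimator(algorithm: str, task: str, seed: int):
    if task == "classification":
        if algorithm == "svm_rbf":
            # calibrated wrapper provides class probabilities for stacking
            return CalibratedClassifierCV(SVC(kernel="rbf",
                                              random_state=seed),
                                          ensemble=False)
        if algorithm == "random_forest":
            return RandomForestClassifier(random_state=seed, n_jobs=1)
        if algorithm == "grad_boost":
            return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                                 eval_metric="logloss")
    else:
        if algorithm == "svm_rbf":
            return SVR(kernel="rbf")
        if algorithm == "random_forest":
            return RandomForestRegressor(random_state=seed, n_jobs=1)
        if algorithm == "grad_boost":
            return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
    raise ValueError(f"unsupported algorithm {algorithm!r} for {task}")


class TopKSelector(BaseEstimator, TransformerMixin):
    """Select the top-k columns of a precomputed importance ranking."""

    def __init__(self, ranking: list[int] | None = None, k="all"):
        self.ranking = ranking
        self.k = k

    def fit(self, X, y=None):
        d = _values(X).shape[1]
        ranking = self.ranking if self.ranking is not None else list(range(d))
        k = d if self.k == "all" else min(int(self.k), len(ranking))
        self.idx_ = np.asarray(ranking[:k], dtype=int)
        return self

    def transform(self, X):
        return _values(X)[:, self.idx_]


class _TunedModel(BaseEstimator):
    """Shared grid-search machinery for the tuned QSAR estimators."""

    def __init__(self, algorithm="svm_rbf", param_grid=None, cv_folds=5,
                 cv_repeats=10, random_state=0, dnn_params=None):
        self.algorithm = algorithm
        self.param_grid = param_grid
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.random_state = random_state
        self.dnn_params = dnn_params

    _task: str = ""

    def _grid(self):
        if self.param_grid is not None:
            return self.param_grid
        return DEFAULT_GRIDS[self._task][self.algorithm]

    def _fit_grid(self, X, y, extra_steps=None, extra_grid=None):
        from sklearn.pipeline import Pipeline

        values = _values(X)
        y = np.asarray(y)
        if self._task == "classification" and len(np.unique(y)) < 2:
            raise ValueError("degenerate training labels")
        if self.algorithm == "dnn":
            params = dict(self.dnn_params or {})
            params.setdefault("random_state", self.random_state)
            params.setdefault("cv_folds", self.cv_folds)
            dnn_cls = (DNNClassifier if self._task == "classification"
                       else DNNRegressor)
            self.best_estimator_ = dnn_cls(**params).fit(values, y)
            self.best_params_ = {"n_epochs": self.best_estimator_.n_epochs_}
            return self
        base = _base_estimator(self.algorithm, self._task, self.random_state)
        steps = (extra_steps or []) + [("est", base)]
        pipe = Pipeline(steps)
        # the calibrated SVM wrapper nests its hyperparameters one level down
        prefix = ("est__estimator__"
                  if isinstance(base, CalibratedClassifierCV) else "est__")
        grid = {f"{prefix}{k}": v for k, v in self._grid().items()}
        grid.update(extra_grid or {})
        if self._task == "classification":
            cv = RepeatedStratifiedKFold(n_splits=self.cv_folds,
                                         n_repeats=self.cv_repeats,
                                         random_state=self.random_state)
            scoring = MCC_SCORER
        else:
            cv = RepeatedKFold(n_splits=self.cv_folds,
                               n_repeats=self.cv_repeats,
                               random_state=self.random_state)
            scoring = "neg_mean_squared_error"
        search = GridSearchCV(pipe, grid, scoring=scoring, cv=cv, n_jobs=1,
                              refit=True)
        search.fit(values, y)
        self.best_estimator_ = search.best_estimator_
        self.best_params_ = {k.removeprefix(prefix): v
                             for k, v in search.best_params_.items()}
        self.cv_results_ = search.cv_results_
        return self

    def predict(self, X):
        return self.best_estimator_.predict(_values(X))


class QSARClassifier(ClassifierMixin, _TunedModel):
    """Tuned binary activity classifier (high = 1, weak = 0).

    Model selection maximizes the mean cross-validated Matthews correlation
    coefficient over the hyperparameter grid.
    """

    _task = "classification"

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self._fit_grid(X, y)

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(_values(X))


class QSARRegressor(RegressorMixin, _TunedModel):
    """Tuned pIC50 regressor; selection by smallest mean CV MSE.

    When ``descriptor_ranking`` (an RF-RFE importance ordering of column
    indices) is given, the number of retained top descriptors is searched
    alongside the estimator grid.
    """

    _task = "regression"

    def __init__(self, algorithm="svm_rbf", param_grid=None, cv_folds=5,
                 cv_repeats=10, random_state=0, dnn_params=None,
                 descriptor_ranking=None, n_descriptors_grid=None):
        super().__init__(algorithm, param_grid, cv_folds, cv_repeats,
                         random_state, dnn_params)
        self.descriptor_ranking = descriptor_ranking
        self.n_descriptors_grid = n_descriptors_grid

    def fit(self, X, y):
        if self.descriptor_ranking is None or self.algorithm == "dnn":
            return self._fit_grid(X, y)
        kgrid = self.n_descriptors_grid or DEFAULT_N_DESCRIPTORS_GRID
        d = _values(X).shape[1]
        kgrid = sorted({d if k == "all" else min(int(k), d) for k in kgrid})
        return self._fit_grid(
            X, y,
            extra_steps=[("topk", TopKSelector(list(self.descriptor_ranking)))],
            extra_grid={"topk__k": kgrid},
        )


class _DNNBase(BaseEstimator):
    """Four-hidden-layer feed-forward net with CV-based epoch selection.

    The net uses ReLU activations and the Adam optimizer at learning rate
    1e-4. The training epoch count is chosen by early stopping (patience on
    the validation metric) inside repeated 5-fold cross-validation; the
    final model is retrained on all training data for the median stopped
    epoch. Everything is seeded.
    """

    def __init__(self, hidden_layer_sizes=(256, 128, 64, 32),
                 learning_rate=1e-4, patience=50, max_epochs=500,
                 cv_folds=5, cv_repeats=5, batch_size="auto",
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.patience = patience
        self.max_epochs = max_epochs
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.batch_size = batch_size
        self.random_state = random_state

    _task = ""

    def _new_net(self, seed: int):
        cls = MLPClassifier if self._task == "classification" else MLPRegressor
        return cls(hidden_layer_sizes=self.hidden_layer_sizes,
                   activation="relu", solver="adam",
                   learning_rate_init=self.learning_rate,
                   batch_size=self.batch_size,
                   max_iter=1, warm_start=True, random_state=seed)

    def _val_score(self, net, X, y) -> float:
        """Higher is better: accuracy, or negative MSE."""
        if self._task == "classification":
            return float(np.mean(net.predict(X) == y))
        return -float(np.mean((net.predict(X) - y) ** 2))

    def _run_epochs(self, X_tr, y_tr, X_val, y_val, seed, n_epochs=None):
        """Train one net; returns (net, best_epoch) using patience if
        ``n_epochs`` is None, else trains exactly ``n_epochs``."""
        net = self._new_net(seed)
        best, best_epoch, since = -np.inf, 1, 0
        limit = n_epochs or self.max_epochs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for epoch in range(1, limit + 1):
                net.fit(X_tr, y_tr)
                if not np.all(np.isfinite(net.loss_curve_[-1:])):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                if n_epochs is None:
                    score = self._val_score(net, X_val, y_val)
                    if score > best + 1e-12:
                        best, best_epoch, since = score, epoch, 0
                    else:
                        since += 1
                        if since >= self.patience:
                            break
        return net, best_epoch

    def fit(self, X, y):
        X = _values(X)
        y = np.asarray(y)
        stopped_epochs = []
        for rep in range(self.cv_repeats):
            seed = self.random_state + rep
            splitter = (StratifiedKFold if self._task == "classification"
                        else KFold)(n_splits=self.cv_folds, shuffle=True,
                                    random_state=seed)
            for fold, (tr, val) in enumerate(splitter.split(X, y)):
                _, best_epoch = self._run_epochs(
                    X[tr], y[tr], X[val], y[val],
                    seed=self.random_state + 1000 * rep + fold)
                stopped_epochs.append(best_epoch)
        self.stopped_epochs_ = stopped_epochs
        self.n_epochs_ = int(np.ceil(np.median(stopped_epochs)))
        self.net_, _ = self._run_epochs(X, y, None, None,
                                        seed=self.random_state,
                                        n_epochs=self.n_epochs_)
        return self

    def predict(self, X):
        return self.net_.predict(_values(X))


class DNNClassifier(ClassifierMixin, _DNNBase):
    """DNN activity classifier; epoch chosen on validation accuracy."""

    _task = "classification"

    def fit(self, X, y):
        self.classes_ = np.unique(np.asarray(y))
        return super().fit(X, y)

    def predict_proba(self, X):
        return self.net_.predict_proba(_values(X))


class DNNRegressor(RegressorMixin, _DNNBase):
    """DNN pIC50 regressor; epoch chosen on validation MSE."""

    _task = "regression"


@dataclass
class TrainedModel:
    """A fitted estimator together with its featurization contract."""

    estimator: object
    task: str
    algorithm: str
    feature_names: list[str]
    featurization: str = ""
    dataset_id: str = ""
    repeat: int = 0
    seed: int = 0
    best_params: dict = field(default_factory=dict)

    def _check(self, X):
        if isinstance(X, FeatureMatrix) and X.feature_names != self.feature_names:
            raise ValueError("feature names do not match the model contract")
        return _values(X)

    def predict(self, X):
        return self.estimator.predict(self._check(X))

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class (highly active) probability."""
        proba = self.estimator.predict_proba(self._check(X))
        return proba[:, -1]

    def manifest(self) -> dict:
        return {
            "task": self.task, "algorithm": self.algorithm,
            "featurization": self.featurization,
            "dataset_id": self.dataset_id, "repeat": self.repeat,
            "seed": self.seed, "best_params": self.best_params,
            "n_features": len(self.feature_names),
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), default=str))


def tune_and_train(config_or_algorithm, fm_train, y_train, task=None,
                   **kwargs) -> TrainedModel:
    """Grid-search tune one model family and refit on the training data.

    ``config_or_algorithm`` is an algorithm name; keyword arguments are
    forwarded to :class:`QSARClassifier` / :class:`QSARRegressor`.
    """
    algorithm = config_or_algorithm
    if task is None:
        y_arr = np.asarray(y_train)
        task = ("classification"
                if y_arr.dtype.kind in "biu" and len(np.unique(y_arr)) <= 2
                else "regression")
    est_cls = QSARClassifier if task == "classification" else QSARRegressor
    est = est_cls(algorithm=algorithm, **kwargs).fit(fm_train, y_train)
    names = (list(fm_train.feature_names)
             if isinstance(fm_train, FeatureMatrix)
             else [f"f{i}" for i in range(_values(fm_train).shape[1])])
    return TrainedModel(
        estimator=est, task=task, algorithm=algorithm, feature_names=names,
        seed=kwargs.get("random_state", 0), best_params=est.best_params_,
    )


def train_dnn(fm_train, y_train, task="classification",
              **dnn_params) -> TrainedModel:
    """Train a DNN under the repeated-CV epoch-selection protocol."""
    cls = DNNClassifier if task == "classification" else DNNRegressor
    est = cls(**dnn_params).fit(fm_train, y_train)
    names = (list(fm_train.feature_names)
             if isinstance(fm_train, FeatureMatrix)
             else [f"f{i}" for i in range(_values(fm_train).shape[1])])
    return TrainedModel(estimator=est, task=task, algorithm="dnn",
                        feature_names=names,
                        seed=dnn_params.get("random_state", 0),
                        best_params={"n_epochs": est.n_epochs_})


def evaluate_classifier(model, partitions: dict) -> dict:
    """Q (%) and MCC per named partition ``{name: (X, y)}``."""
    out = {}
    for name, (X, y) in partitions.items():
        c = confusion(y, model.predict(X))
        out[name] = {"Q": q_accuracy(c), "MCC": mcc(c)}
    return out


def evaluate_regressor(model, partitions: dict) -> dict:
    """R² and RMSE per named partition ``{name: (X, y)}``."""
    out = {}
    for name, (X, y) in partitions.items():
        y_hat = model.predict(X)
        out[name] = {"R2": r2(y, y_hat), "RMSE": rmse(y, y_hat)}
    return out


def summarize_reports(reports: list[dict]) -> dict:
    """Mean and std of each metric across repeats.

    ``reports`` is a list of per-repeat outputs of the evaluate_* helpers.
    """
    out: dict = {}
    for part in reports[0]:
        out[part] = {}
        for metric in reports[0][part]:
            vals = np.array([r[part][metric] for r in reports])
            out[part][metric] = {"mean": float(vals.mean()),
                                 "std": float(vals.std(ddof=0))}
    return out


def experiment_grid(datasets, featurizations, algorithms,
                    n_repeats: int = 10) -> list[dict]:
    """Full factorial job list: one job per (dataset, repeat, featurization,
    algorithm), in stable nested order."""
    if not (list(datasets) and list(featurizations) and list(algorithms)):
        raise ValueError("all factors must be non-empty")
    jobs = []
    for ds, rep, feat, algo in itertools.product(
            datasets, range(n_repeats), featurizations, algorithms):
        jobs.append({"dataset": ds, "repeat": rep, "featurization": feat,
                     "algorithm": algo})
    return jobs
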