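"""Stacked-generalization ensembles of fingerprint-specific classifiers.

Three classifiers of the same algorithm, each trained on a different
fingerprint representation (MACCS / Avalon / ECFP4) of the same molecules,
are combined by a logistic-regression meta-learner over their predicted
positive-class probabilities. Meta-training uses out-of-fold base
probabilities on the training partition to avoid leakage; an in-sample flag
is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .featurize import FeatureMatrix
from .models import TrainedModel


def _values(X):
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)


class StackedFingerprintClassifier(ClassifierMixin, BaseEstimator):
    """Logistic-regression stack over per-fingerprint base classifiers.

    Parameters
    ----------
    base_models : dict[str, TrainedModel]
        Fitted base classifiers keyed by fingerprint kind; all must have
        been trained on the same molecules of the same repeat.
    n_folds : int
        Folds used to produce out-of-fold meta-features.
    in_sample : bool
        If True, meta-features are the bases' in-sample training
        probabilities instead of out-of-fold ones.
    """

    def __init__(self, base_models: dict[str, TrainedModel] | None = None,
                 n_folds: int = 5, in_sample: bool = False,
                 random_state: int = 0):
        self.base_models = base_models
        self.n_folds = n_folds
        self.in_sample = in_sample
        self.random_state = random_state

    @property
    def kinds_(self) -> list[str]:
        return sorted(self.base_models)

    def fit(self, X_per_kind: dict[str, FeatureMatrix], y):
        if not self.base_models:
            raise ValueError("base_models must be provided")
        missing = set(self.base_models) - set(X_per_kind)
        if missing:
            raise ValueError(f"missing training features for {sorted(missing)}")
        y = np.asarray(y)
        n = len(y)
        kinds = self.kinds_
        meta = np.empty((n, len(kinds)))
        if self.in_sample:
            for j, kind in enumerate(kinds):
                meta[:, j] = self.base_models[kind].predict_proba(
                    X_per_kind[kind])
        else:
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                                  random_state=self.random_state)
            for j, kind in enumerate(kinds):
                base = self.base_models[kind]
                # refit the tuned estimator (chosen hyperparameters), not
                # the tuning wrapper, in each fold
                inner = getattr(base.estimator, "best_estimator_",
                                base.estimator)
                values = _values(X_per_kind[kind])
                for tr, val in skf.split(values, y):
                    refit = clone(inner)
                    refit.fit(values[tr], y[tr])
                    meta[val, j] = refit.predict_proba(values[val])[:, -1]
        # effectively unregularized meta-learner (numerical stability only)
        self.meta_ = LogisticRegression(C=np.inf, max_iter=1000,
                                        random_state=self.random_state)
        self.meta_.fit(meta, y)
        self.classes_ = self.meta_.classes_
        return self

    def _meta_features(self, X_per_kind: dict[str, FeatureMatrix]):
        cols = []
        for kind in self.kinds_:
            if kind not in X_per_kind:
                raise ValueError(f"missing features for fingerprint {kind!r}")
            cols.append(self.base_models[kind].predict_proba(X_per_kind[kind]))
        return np.column_stack(cols)

    def predict_proba(self, X_per_kind: dict[str, FeatureMatrix]) -> np.ndarray:
        return self.meta_.predict_proba(self._meta_features(X_per_kind))

    def predict(self, X_per_kind: dict[str, FeatureMatrix]) -> np.ndarray:
        """Label 1 (high) iff stacked positive probability ≥ 0.5."""
        return (self.predict_proba(X_per_kind)[:, -1] >= 0.5).astype(int)

    def coefficients(self) -> dict:
        """Human-readable meta-learner weights per base fingerprint."""
        return {
            "intercept": float(self.meta_.intercept_[0]),
            "weights": {k: float(w) for k, w in
                        zip(self.kinds_, self.meta_.coef_[0])},
        }

    def save_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kinds": self.kinds_, "in_sample": self.in_sample,
            "meta": self.coefficients(),
        }))


def fit_stack(base_models: dict[str, TrainedModel],
              X_per_kind: dict[str, FeatureMatrix], y,
              seed: int = 0, **kwargs) -> StackedFingerprintClassifier:
    """Fit the logistic meta-learner over the given fitted base models."""
    return StackedFingerprintClassifier(
        base_models, random_state=seed, **kwargs).fit(X_per_kind, y)


def predict_stack(model: StackedFingerprintClassifier,
                  X_per_kind: dict[str, FeatureMatrix]):
    """(positive probability, label) for candidates under a fitted stack."""
    proba = model.predict_proba(X_per_kind)[:, -1]
    return proba, (proba >= 0.5).astype(int)
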