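"""End-to-end study runner: benchmark in, screened candidates out.

Wires the pieces together the way a full screening study uses them:
fingerprint featurization with train-fitted variance filtering for the
classification arm; descriptor featurization with correlation filtering,
RF-RFE ranking and [0.1, 0.9] auto-scaling for the regression arm; tuned
models per (featurization, algorithm); stacked ensembles per algorithm;
model selection on the external validation set; a SOM activity landscape;
and the final cascade over the unlabeled screening library.

Grid sizes here are desk-scale defaults chosen so a full study runs in
minutes on one CPU; every grid is an argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import (CascadeConfig, CascadeModel, ScreeningResult,
                      run_cascade, select_models)
from .datasets import stratified_split
from .ensemble import StackedFingerprintClassifier
from .featurize import (CorrelationFilter, DescriptorFeaturizer,
                        FeatureMatrix, FingerprintFeaturizer, IntervalScaler,
                        RFRFERanker, VarianceQuartileFilter)
from .metrics import confusion, mcc, rmse
from .models import QSARClassifier, QSARRegressor, TrainedModel
from .pains_filter import AggregatorSet
from .som import SOMActivityLandscape
from .synthetic import Benchmark

#: Small tuning grids for desk-scale studies (config-exposed).
SMALL_GRIDS = {
    "classification": {
        "svm_rbf": {"C": [1, 10, 100], "gamma": [0.01, 0.1]},
        "random_forest": {"n_estimators": [300], "max_leaf_nodes": [512, None]},
        "grad_boost": {"n_estimators": [300], "max_depth": [6],
                       "subsample": [0.8], "colsample_bytree": [0.8]},
    },
    "regression": {
        "svm_rbf": {"C": [1, 10, 100], "gamma": [0.01, 0.1],
                    "epsilon": [0.1]},
        "random_forest": {"n_estimators": [300], "max_leaf_nodes": [512, None]},
        "grad_boost": {"n_estimators": [300], "max_depth": [6],
                       "subsample": [0.8], "colsample_bytree": [0.8]},
    },
}


@dataclass
class StudyResult:
    """Everything a screening study produces."""

    base_test_mcc: dict = field(default_factory=dict)      # (fp, algo) -> MCC
    base_external_mcc: dict = field(default_factory=dict)
    stacked_test_mcc: dict = field(default_factory=dict)   # algo -> MCC
    stacked_external_mcc: dict = field(default_factory=dict)
    regressor_test_rmse: dict = field(default_factory=dict)  # (set, algo) -> RMSE
    regressor_external_rmse: dict = field(default_factory=dict)
    selected_classifiers: list = field(default_factory=list)
    selected_regressors: list = field(default_factory=list)
    som: SOMActivityLandscape | None = None
    screening_results: list[ScreeningResult] = field(default_factory=list)
    recall_planted_actives: float | None = None
    n_planted_inactives_passed: int | None = None
    n_passed: int | None = None


def _fp_key(kind: str) -> str:
    return f"fp:{kind}"


def _desc_key(set_id: str) -> str:
    return f"desc:{set_id}"


def run_study(bench: Benchmark, seed: int = 0,
              fingerprint_kinds=("maccs166", "avalon1024", "ecfp4_1024"),
              algorithms=("svm_rbf", "random_forest", "grad_boost"),
              descriptor_sets=("fragment_counts", "physchem_2d"),
              grids=None, test_fraction: float = 0.2,
              cv_repeats: int = 1, rfe_estimators: int = 100,
              n_descriptors_grid=(20, "all"),
              n_select_classifiers: int = 6, n_select_regressors: int = 4,
              som_shape: tuple[int, int] = (10, 11),
              aggregators: AggregatorSet | None = None,
              cascade_config: CascadeConfig | None = None) -> StudyResult:
    """Run the full study on a synthetic benchmark.

    One stratified train/test split drives tuning and test evaluation; the
    benchmark's external sets drive model selection for the screen.
    """
    grids = grids or SMALL_GRIDS
    result = StudyResult()

    # ----- classification arm -------------------------------------------
    cls_ds = bench.classification
    y = cls_ds.y
    train, test = stratified_split(cls_ds, test_fraction, seed=seed)
    y_ext = bench.external_classification.y

    cls_features_train: dict[str, FeatureMatrix] = {}
    cls_features_test: dict[str, FeatureMatrix] = {}
    cls_features_ext: dict[str, FeatureMatrix] = {}
    screen_features: dict[str, FeatureMatrix] = {}
    for kind in fingerprint_kinds:
        feat = FingerprintFeaturizer(kind)
        fm_all = feat.transform(cls_ds.records)
        vf = VarianceQuartileFilter().fit(fm_all.subset_rows(train))
        cls_features_train[_fp_key(kind)] = vf.transform(fm_all).subset_rows(train)
        cls_features_test[_fp_key(kind)] = vf.transform(fm_all).subset_rows(test)
        cls_features_ext[_fp_key(kind)] = vf.transform(
            feat.transform(bench.external_classification.records))
        screen_features[_fp_key(kind)] = vf.transform(
            feat.transform(bench.screening_library))

    base_models: dict[tuple[str, str], TrainedModel] = {}
    for kind in fingerprint_kinds:
        key = _fp_key(kind)
        for algo in algorithms:
            clf = QSARClassifier(
                algorithm=algo,
                param_grid=grids["classification"].get(algo),
                cv_repeats=cv_repeats, random_state=seed,
            ).fit(cls_features_train[key], y[train])
            model = TrainedModel(
                estimator=clf, task="classification", algorithm=algo,
                feature_names=list(cls_features_train[key].feature_names),
                featurization=kind, seed=seed, best_params=clf.best_params_)
            base_models[(kind, algo)] = model
            result.base_test_mcc[(kind, algo)] = mcc(confusion(
                y[test], model.predict(cls_features_test[key])))
            result.base_external_mcc[(kind, algo)] = mcc(confusion(
                y_ext, model.predict(cls_features_ext[key])))

    stacks: dict[str, StackedFingerprintClassifier] = {}
    fp_map = {kind: _fp_key(kind) for kind in fingerprint_kinds}
    for algo in algorithms:
        bases = {kind: base_models[(kind, algo)] for kind in fingerprint_kinds}
        stack = StackedFingerprintClassifier(
            bases, random_state=seed).fit(
            {k: cls_features_train[v] for k, v in fp_map.items()}, y[train])
        stacks[algo] = stack
        result.stacked_test_mcc[algo] = mcc(confusion(
            y[test], stack.predict(
                {k: cls_features_test[v] for k, v in fp_map.items()})))
        result.stacked_external_mcc[algo] = mcc(confusion(
            y_ext, stack.predict(
                {k: cls_features_ext[v] for k, v in fp_map.items()})))

    # ----- regression arm ------------------------------------------------
    reg_ds = bench.regression
    y_reg = reg_ds.y
    rtrain, rtest = stratified_split(reg_ds, test_fraction, seed=seed)
    y_reg_ext = bench.external_regression.y

    reg_models: dict[tuple[str, str], TrainedModel] = {}
    reg_features_test: dict[str, FeatureMatrix] = {}
    reg_features_ext: dict[str, FeatureMatrix] = {}
    for set_id in descriptor_sets:
        key = _desc_key(set_id)
        featurizer = DescriptorFeaturizer(set_id).fit(
            [reg_ds.records[i] for i in rtrain])
        fm_all = featurizer.transform(reg_ds.records)
        cf = CorrelationFilter().fit(fm_all.subset_rows(rtrain), y_reg[rtrain])
        fm_all = cf.transform(fm_all)
        scaler = IntervalScaler().fit(fm_all.subset_rows(rtrain))
        fm_all = scaler.transform(fm_all)
        fm_train = fm_all.subset_rows(rtrain)
        ranking = RFRFERanker(n_estimators=rfe_estimators,
                              random_state=seed).fit(
            fm_train, y_reg[rtrain]).ranking_idx_
        reg_features_test[key] = fm_all.subset_rows(rtest)
        fm_ext = scaler.transform(cf.transform(
            featurizer.transform(bench.external_regression.records)))
        reg_features_ext[key] = fm_ext
        screen_features[key] = scaler.transform(cf.transform(
            featurizer.transform(bench.screening_library)))
        for algo in algorithms:
            reg = QSARRegressor(
                algorithm=algo, param_grid=grids["regression"].get(algo),
                cv_repeats=cv_repeats, random_state=seed,
                descriptor_ranking=list(ranking),
                n_descriptors_grid=list(n_descriptors_grid),
            ).fit(fm_train, y_reg[rtrain])
            model = TrainedModel(
                estimator=reg, task="regression", algorithm=algo,
                feature_names=list(fm_train.feature_names),
                featurization=set_id, seed=seed, best_params=reg.best_params_)
            reg_models[(set_id, algo)] = model
            result.regressor_test_rmse[(set_id, algo)] = rmse(
                y_reg[rtest], model.predict(reg_features_test[key]))
            result.regressor_external_rmse[(set_id, algo)] = rmse(
                y_reg_ext, model.predict(fm_ext))

    # ----- model selection on the external sets --------------------------
    cls_scores = {f"{kind}|{algo}": result.base_external_mcc[(kind, algo)]
                  for (kind, algo) in base_models}
    cls_scores.update({f"stack|{algo}": result.stacked_external_mcc[algo]
                       for algo in stacks})
    chosen_cls = select_models(cls_scores,
                               top_k=min(n_select_classifiers,
                                         len(cls_scores)))
    reg_scores = {f"{set_id}|{algo}": result.regressor_external_rmse[(set_id, algo)]
                  for (set_id, algo) in reg_models}
    chosen_reg = select_models(reg_scores,
                               top_k=min(n_select_regressors, len(reg_scores)),
                               higher_is_better=False)
    result.selected_classifiers = chosen_cls
    result.selected_regressors = chosen_reg

    cascade_classifiers = []
    for name in chosen_cls:
        first, algo = name.split("|")
        if first == "stack":
            cascade_classifiers.append(
                CascadeModel(stacks[algo], fp_map, model_id=name))
        else:
            cascade_classifiers.append(
                CascadeModel(base_models[(first, algo)], _fp_key(first),
                             model_id=name))
    cascade_regressors = [
        CascadeModel(reg_models[tuple(name.split("|"))],
                     _desc_key(name.split("|")[0]), model_id=name)
        for name in chosen_reg
    ]

    # ----- SOM activity landscape ----------------------------------------
    som_key = _fp_key("ecfp4_1024")
    som = SOMActivityLandscape(width=som_shape[0], height=som_shape[1],
                               random_state=seed)
    som.fit(cls_features_train[som_key], y[train])
    result.som = som

    # ----- cascade screen -------------------------------------------------
    results = run_cascade(
        bench.screening_library, cascade_classifiers, cascade_regressors,
        som, som_key, aggregators, screen_features,
        cascade_config or CascadeConfig())
    result.screening_results = results

    truth = bench.ground_truth.set_index("id")["planted"]
    passed = {r.id for r in results if r.status == "passed"}
    actives = set(truth[truth == "active"].index)
    inactives = set(truth[truth == "inactive"].index)
    result.n_passed = len(passed)
    result.recall_planted_actives = (len(passed & actives) / len(actives)
                                     if actives else None)
    result.n_planted_inactives_passed = len(passed & inactives)
    return result
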