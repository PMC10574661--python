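"""Cascade stage rules, model selection and screening audit."""

import numpy as np
import pytest

import qsarscreen as qs
from qsarscreen.cascade import CascadeConfig, CascadeModel
from qsarscreen.featurize import FeatureMatrix


class _ColumnLabel:
    """Stub classifier: label = indicated column of the feature block."""

    def __init__(self, col=0):
        self.col = col

    def predict(self, X):
        return np.asarray(X)[:, self.col].astype(int)


class _ColumnValue:
    """Stub regressor: predicted pIC50 = indicated column."""

    def __init__(self, col=0, offset=0.0):
        self.col = col
        self.offset = offset

    def predict(self, X):
        return np.asarray(X)[:, self.col] + self.offset


class TestSelectModels:
    def test_top_one_is_argmax(self):
        assert qs.select_models({"a": 0.5, "b": 0.9, "c": 0.7},
                                top_k=1) == ["b"]

    def test_threshold_above_all_errors(self):
        with pytest.raises(ValueError, match="empty selection"):
            qs.select_models({"a": 0.5, "b": 0.6}, threshold=0.99)

    def test_select_all(self):
        scores = {f"m{i}": 0.5 + 0.001 * i for i in range(39)}
        assert len(qs.select_models(scores, top_k=39)) == 39

    def test_ties_broken_by_model_id(self):
        assert qs.select_models({"b": 0.5, "a": 0.5}, top_k=1) == ["a"]

    def test_lower_is_better_for_error_metrics(self):
        assert qs.select_models({"a": 0.3, "b": 0.2}, top_k=1,
                                higher_is_better=False) == ["b"]


class TestConsensusAndPotency:
    def test_consensus_rules(self):
        # 4 classifiers vote via 4 feature columns
        X = np.array([[1, 1, 1, 1], [1, 1, 1, 0], [0, 0, 0, 0]], float)
        features = {"f": FeatureMatrix(X, list("abcd"), "fingerprint")}
        clfs = [CascadeModel(_ColumnLabel(i), "f") for i in range(4)]
        n_pos, keep_unanimous = qs.consensus_classify(clfs, features,
                                                      fraction=1.0)
        assert n_pos.tolist() == [4, 3, 0]
        assert keep_unanimous.tolist() == [True, False, False]
        _, keep_half = qs.consensus_classify(clfs, features, fraction=0.5)
        assert keep_half.tolist() == [True, True, False]

    def test_average_potency_and_strict_cut(self):
        X = np.array([[6.0, 6.0], [5.0, 5.0], [4.0, 6.0]])
        features = {"d": FeatureMatrix(X, ["p1", "p2"], "descriptor")}
        regs = [CascadeModel(_ColumnValue(0), "d"),
                CascadeModel(_ColumnValue(1), "d")]
        mean_p, ic50, keep = qs.average_potency(regs, features, cut_um=10.0)
        assert mean_p.tolist() == [6.0, 5.0, 5.0]
        assert ic50 == pytest.approx([1.0, 10.0, 10.0])
        # exactly 10 μM fails the strict "<" rule
        assert keep.tolist() == [True, False, False]

    def test_single_regressor_mean_is_itself(self):
        X = np.array([[7.5]])
        features = {"d": FeatureMatrix(X, ["p"], "descriptor")}
        mean_p, _, _ = qs.average_potency(
            [CascadeModel(_ColumnValue(0), "d")], features)
        assert mean_p[0] == 7.5


def _screen_setup(n=30, seed=0):
    """A stub screen: feature column 0 = classifier vote, column 1 = pIC50."""
    rng = np.random.default_rng(seed)
    votes = rng.integers(0, 2, n).astype(float)
    pic50 = rng.uniform(4.0, 8.0, n)
    X = np.column_stack([votes, pic50])
    library = [qs.MoleculeRecord(f"mol{i:03d}", "c1ccccc1") for i in range(n)]
    features = {"f": FeatureMatrix(X, ["vote", "act"], "fingerprint",
                                   ids=[r.id for r in library])}
    som = qs.SOMActivityLandscape(width=2, height=1, n_epochs=1)
    som.weights_ = np.array([[1.0, 7.0], [0.0, 4.5]])
    som.hp_ = np.array([1.0, 0.0])
    som.n_total_ = np.array([1, 1])
    som.n_high_ = np.array([1, 0])
    clfs = [CascadeModel(_ColumnLabel(0), "f", model_id="c1")]
    regs = [CascadeModel(_ColumnValue(1), "f", model_id="r1")]
    return library, clfs, regs, som, features


class TestRunCascade:
    def test_empty_library(self):
        library, clfs, regs, som, features = _screen_setup(n=1)
        empty = {"f": features["f"].subset_rows([])}
        assert qs.run_cascade([], clfs, regs, som, "f", None, empty) == []

    def test_every_molecule_appears_exactly_once(self):
        library, clfs, regs, som, features = _screen_setup()
        results = qs.run_cascade(library, clfs, regs, som, "f", None,
                                 features)
        assert sorted(r.id for r in results) == sorted(r.id for r in library)

    def test_short_circuit_audit(self):
        library, clfs, regs, som, features = _screen_setup()
        results = qs.run_cascade(library, clfs, regs, som, "f", None,
                                 features)
        for r in results:
            if r.status == "failed@classify":
                assert "potency" not in r.audit and r.mean_pic50 is None
            if r.status == "failed@potency":
                assert "hp" not in r.audit
            if r.status == "passed":
                assert set(r.audit) == {"classify", "potency", "hp",
                                        "aggregator"}

    def test_passed_ranked_by_ascending_ic50(self):
        library, clfs, regs, som, features = _screen_setup(seed=3)
        results = qs.run_cascade(library, clfs, regs, som, "f", None,
                                 features)
        passed = [r for r in results if r.status == "passed"]
        ic50s = [r.implied_ic50_um for r in passed]
        assert ic50s == sorted(ic50s)
        assert results[:len(passed)] == passed

    def test_monotone_in_potency_cut(self):
        library, clfs, regs, som, features = _screen_setup(seed=4)
        def passed_at(cut):
            res = qs.run_cascade(library, clfs, regs, som, "f", None,
                                 features,
                                 CascadeConfig(potency_cut_um=cut))
            return {r.id for r in res if r.status == "passed"}
        assert passed_at(1.0) <= passed_at(10.0) <= passed_at(100.0)

    def test_monotone_in_hp_threshold(self):
        library, clfs, regs, som, features = _screen_setup(seed=5)
        def passed_at(hp):
            res = qs.run_cascade(library, clfs, regs, som, "f", None,
                                 features, CascadeConfig(hp_threshold=hp))
            return {r.id for r in res if r.status == "passed"}
        assert passed_at(1.0) <= passed_at(0.8) <= passed_at(0.0)

    def test_implied_ic50_consistent_with_mean_pic50(self):
        library, clfs, regs, som, features = _screen_setup(seed=6)
        for r in qs.run_cascade(library, clfs, regs, som, "f", None,
                                features):
            if r.mean_pic50 is not None:
                assert r.implied_ic50_um == pytest.approx(
                    10 ** (6 - r.mean_pic50))

    def test_aggregator_stage_drops_flagged(self):
        library, clfs, regs, som, features = _screen_setup(seed=7)
        aggset = qs.AggregatorSet.from_records(
            [qs.standardize("c1ccccc1", id="agg0")])  # every library molecule
        results = qs.run_cascade(library, clfs, regs, som, "f", aggset,
                                 features)
        assert not any(r.status == "passed" for r in results)
        assert any(r.status == "failed@aggregator" for r in results)

    def test_results_table_columns(self):
        library, clfs, regs, som, features = _screen_setup()
        table = qs.results_table(
            qs.run_cascade(library, clfs, regs, som, "f", None, features))
        assert {"id", "status", "predicted_ic50_um", "som_hp"} <= set(table)
        assert len(table) == len(library)

    def test_needs_models(self):
        library, clfs, regs, som, features = _screen_setup()
        with pytest.raises(ValueError):
            qs.run_cascade(library, [], regs, som, "f", None, features)
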