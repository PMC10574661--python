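"""Fingerprints, descriptors, filters, ranking and interval scaling."""

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

import qsarscreen as qs
from qsarscreen.featurize import FeatureMatrix


class TestFingerprints:
    @pytest.mark.parametrize("kind,d", [
        ("maccs166", 166), ("avalon1024", 1024), ("ecfp4_1024", 1024),
    ])
    def test_dimensions(self, simple_records, kind, d):
        fm = qs.fingerprints(simple_records, kind)
        assert fm.d == d
        assert fm.n == len(simple_records)
        assert set(np.unique(fm.values)) <= {0.0, 1.0}
        assert fm.kind == "fingerprint"

    def test_identical_smiles_identical_rows(self):
        recs = [qs.standardize("Cc1ccccc1", id=i) for i in "ab"]
        fm = qs.fingerprints(recs, "ecfp4_1024")
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_ecfp4_bits_match_toolkit(self):
        # the benzene row must equal an independently computed bit vector
        mol = Chem.MolFromSmiles("c1ccccc1")
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        expected = np.zeros(1024)
        expected[list(gen.GetFingerprint(mol).GetOnBits())] = 1
        fm = qs.fingerprints([qs.standardize("c1ccccc1", id="b")],
                             "ecfp4_1024")
        assert np.array_equal(fm.values[0], expected)

    def test_unsupported_kind(self, simple_records):
        with pytest.raises(ValueError):
            qs.fingerprints(simple_records, "daylight")


class TestDescriptors:
    def test_ethanol_physchem_values(self):
        fm = qs.descriptors([qs.standardize("CCO", id="e")], "physchem_2d")
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["MolWt"] == pytest.approx(46.07, abs=0.01)
        assert row["HeavyAtomCount"] == 3

    def test_benzene_fragment_counts(self):
        fm = qs.descriptors([qs.standardize("c1ccccc1", id="b")],
                            "fragment_counts")
        row = dict(zip(fm.feature_names, fm.values[0]))
        assert row["fr_benzene"] == 1
        assert len(fm.feature_names) == 85

    def test_identical_molecules_identical_rows(self):
        recs = [qs.standardize("CCO", id=i) for i in "ab"]
        fm = qs.descriptors(recs, "physchem_2d")
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_no_missing_values(self, simple_records):
        fm = qs.descriptors(simple_records, "physchem_2d")
        assert np.isfinite(fm.values).all()


class TestVarianceFilter:
    def test_lowest_variance_columns_dropped(self):
        rng = np.random.default_rng(0)
        cols = [np.zeros(20), np.zeros(20)]
        for scale in (0.1, 0.1, 0.2, 0.2, 0.3, 0.3):
            cols.append(rng.normal(0, scale, 20))
        X = np.column_stack(cols)
        fm = FeatureMatrix(X, [f"c{i}" for i in range(8)], "descriptor")
        out = qs.variance_filter(fm, 0.25)
        assert out.d == 6
        assert "c0" not in out.feature_names
        assert "c1" not in out.feature_names

    def test_tie_drops_lowest_index(self):
        X = np.array([[0., 0, 0, 0], [1, 1, 1, 1]])
        fm = FeatureMatrix(X, list("abcd"), "descriptor")
        out = qs.variance_filter(fm, 0.25)
        assert out.feature_names == ["b", "c", "d"]

    def test_never_drops_higher_variance_than_kept(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, rng.uniform(0.1, 2, 12), size=(50, 12))
        fm = FeatureMatrix(X, [f"c{i}" for i in range(12)], "descriptor")
        out = qs.variance_filter(fm)
        dropped = set(fm.feature_names) - set(out.feature_names)
        var = dict(zip(fm.feature_names, X.var(axis=0)))
        assert max(var[c] for c in dropped) <= min(var[c] for c in out.feature_names)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1])
    def test_quartile_bounds(self, q):
        fm = FeatureMatrix(np.eye(3), list("abc"), "descriptor")
        with pytest.raises(ValueError):
            qs.variance_filter(fm, q)


class TestPccFilter:
    def test_duplicated_column_removed_once(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        fm = FeatureMatrix(X, list("abc"), "descriptor")
        out = qs.pcc_filter(fm, rng.normal(size=30), r_cut=0.95)
        assert out.feature_names == ["a", "c"]

    def test_independent_columns_kept(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 2))
        fm = FeatureMatrix(X, list("ab"), "descriptor")
        out = qs.pcc_filter(fm, rng.normal(size=200), r_cut=0.95)
        assert out.d == 2

    def test_single_column_unchanged(self):
        fm = FeatureMatrix(np.arange(5.0)[:, None], ["a"], "descriptor")
        assert qs.pcc_filter(fm, np.arange(5.0)).feature_names == ["a"]

    def test_postcondition_no_offending_pair(self):
        # brute-force check on a matrix with many collinear columns
        rng = np.random.default_rng(4)
        base = rng.normal(size=(60, 3))
        X = np.column_stack([base, base @ rng.normal(size=(3, 5)) +
                             0.01 * rng.normal(size=(60, 5))])
        y = base[:, 0]
        out = qs.pcc_filter(FeatureMatrix(
            X, [f"c{i}" for i in range(8)], "descriptor"), y, r_cut=0.9)
        R = np.corrcoef(out.values.T)
        off_diag = np.abs(R[np.triu_indices(out.d, 1)])
        assert (off_diag <= 0.9).all()

    def test_member_with_higher_response_correlation_survives(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=100)
        good = y + 0.1 * rng.normal(size=100)
        bad = good + 0.01 * rng.normal(size=100)  # near-duplicate, noisier
        X = np.column_stack([bad, good])
        fm = FeatureMatrix(X, ["bad", "good"], "descriptor")
        out = qs.pcc_filter(fm, y, r_cut=0.95)
        kept = out.feature_names
        yc = [abs(np.corrcoef(X[:, i], y)[0, 1]) for i in range(2)]
        assert kept == [["bad", "good"][int(np.argmax(yc))]]


class TestRfRfe:
    def test_planted_signal_ranked_first(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 6))
        y = X[:, 3]  # response equals feature 3 exactly
        fm = FeatureMatrix(X, [f"f{i}" for i in range(6)], "descriptor")
        ranking = qs.rfrfe_rank(fm, y, seed=0, n_estimators=100)
        assert ranking[0] == "f3"

    def test_single_feature(self):
        fm = FeatureMatrix(np.arange(10.0)[:, None], ["only"], "descriptor")
        assert qs.rfrfe_rank(fm, np.arange(10.0), seed=0,
                             n_estimators=20) == ["only"]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5)
        fm = FeatureMatrix(X, [f"f{i}" for i in range(5)], "descriptor")
        r1 = qs.rfrfe_rank(fm, y, seed=3, n_estimators=50)
        r2 = qs.rfrfe_rank(fm, y, seed=3, n_estimators=50)
        assert r1 == r2


class TestAutoscale:
    def test_endpoints_map_to_01_09(self):
        fm = FeatureMatrix(np.array([[0.], [5.], [10.]]), ["a"], "descriptor")
        params = qs.autoscale_fit(fm)
        out = qs.autoscale_apply(fm, params)
        assert out.values[:, 0] == pytest.approx([0.1, 0.5, 0.9])

    def test_constant_column_maps_to_half(self):
        fm = FeatureMatrix(np.full((3, 1), 3.0), ["a"], "descriptor")
        out = qs.autoscale_apply(fm, qs.autoscale_fit(fm))
        assert out.values[:, 0] == pytest.approx([0.5, 0.5, 0.5])

    def test_out_of_range_not_clipped(self):
        train = FeatureMatrix(np.array([[0.], [10.]]), ["a"], "descriptor")
        params = qs.autoscale_fit(train)
        test = FeatureMatrix(np.array([[20.]]), ["a"], "descriptor")
        assert qs.autoscale_apply(test, params).values[0, 0] == pytest.approx(1.7)

    def test_train_min_max_invariant(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4)) * [1, 10, 0.1, 100]
        fm = FeatureMatrix(X, list("abcd"), "descriptor")
        out = qs.autoscale_apply(fm, qs.autoscale_fit(fm))
        assert out.values.min(axis=0) == pytest.approx([0.1] * 4)
        assert out.values.max(axis=0) == pytest.approx([0.9] * 4)

    def test_name_mismatch_errors(self):
        fm = FeatureMatrix(np.eye(2), list("ab"), "descriptor")
        params = qs.autoscale_fit(fm)
        other = FeatureMatrix(np.eye(2), list("xy"), "descriptor")
        with pytest.raises(ValueError):
            qs.autoscale_apply(other, params)

    def test_params_json_round_trip(self, tmp_path):
        fm = FeatureMatrix(np.array([[0., 2.], [4., 8.]]), list("ab"),
                           "descriptor")
        params = qs.autoscale_fit(fm)
        params.to_json(tmp_path / "scaler.json")
        loaded = qs.ScalerParams.from_json(tmp_path / "scaler.json")
        out = qs.autoscale_apply(fm, loaded)
        assert np.allclose(out.values, qs.autoscale_apply(fm, params).values)
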