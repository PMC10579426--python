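"""Train/test validation, prediction tables and structural-location annotation."""

import numpy as np
import pandas as pd
import pytest

from varactivity.gnm import CalphaModel
from varactivity.regression import fit_ols
from varactivity.validate import (
    annotate_location,
    assign_activity_group,
    make_splits,
    predict_variants,
    run_validation,
)
from varactivity.features import FeatureMatrix


class TestSplits:
    def test_study_shape_104_variants(self):
        scheme = make_splits(104, test_size=10, n_splits=20, seed=0)
        assert scheme.n_splits == 20
        for train, test in scheme.splits:
            assert len(test) == 10
            assert len(train) == 94

    def test_same_seed_identical(self):
        assert make_splits(50, seed=3) == make_splits(50, seed=3)
        assert make_splits(50, seed=3) != make_splits(50, seed=4)

    def test_disjoint_and_exhaustive(self):
        scheme = make_splits(37, test_size=5, n_splits=8, seed=1)
        for train, test in scheme.splits:
            assert set(train) & set(test) == set()
            assert sorted(set(train) | set(test)) == list(range(37))

    def test_test_size_too_large(self):
        with pytest.raises(ValueError):
            make_splits(10, test_size=10)


class TestRunValidation:
    def test_noiseless_every_split_perfect(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(0, 1, (60, 3)), columns=list("abc"))
        y = 10.0 + X @ np.array([40.0, -20.0, 15.0])
        scheme = make_splits(60, test_size=10, n_splits=5, seed=2)
        report = run_validation(X, y, scheme)
        assert len(report.table) == 10  # 5 splits × 2 methods
        assert (report.table["test_r2"] > 1 - 1e-8).all()
        assert (report.table["test_rmse"] < 1e-6).all()

    def test_noisy_target_r2_recovered(self, study_dataset):
        # generator R² = 0.9: mean test R² of the true model within ± 0.1
        X = study_dataset.features.values[
            list(study_dataset.truth.informative_names)
        ]
        clean = ~study_dataset.truth.outlier_flags
        scheme = make_splits(int(clean.sum()), seed=11)
        report = run_validation(X[clean], study_dataset.activity[clean], scheme)
        assert abs(report.mean_test_r2("mlr") - 0.9) < 0.1

    def test_top_model_is_max_and_bounded(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0, 1, (50, 4)), columns=list("abcd"))
        y = 5 + X @ np.array([30.0, -10.0, 5.0, 0.0]) + rng.normal(0, 3, 50)
        report = run_validation(X, y, make_splits(50, test_size=8, seed=5))
        for method in ("mlr", "plsr"):
            top = report.top(method)
            sub = report.table[report.table["method"] == method]
            assert top["test_r2"] == sub["test_r2"].max()
            assert top["test_r2"] <= 1.0

    def test_mismatched_scheme_rejected(self):
        X = pd.DataFrame(np.ones((10, 1)), columns=["a"])
        with pytest.raises(ValueError, match="scheme"):
            run_validation(X, np.ones(10), make_splits(20, test_size=3))


class TestPredictVariants:
    def _fitted(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.uniform(0, 1, (40, 2)),
            columns=["s1", "s2"],
            index=[f"RAG1:A{i+1}V" for i in range(40)],
        )
        y = 20.0 + X @ np.array([80.0, -40.0]) + rng.normal(0, 2, 40)
        model = fit_ols(X, y)
        features = FeatureMatrix(
            values=X, categories={"s1": "seq", "s2": "struct"}
        )
        return model, features, X

    def test_activity_group_boundaries(self):
        assert assign_activity_group(19.9) == "AG1"
        assert assign_activity_group(20.0) == "AG2"
        assert assign_activity_group(49.999) == "AG2"
        assert assign_activity_group(50.0) == "AG3"
        assert assign_activity_group(80.0) == "AG4"
        assert assign_activity_group(150.0) == "AG4"

    def test_training_rows_reproduce_fitted_values(self):
        model, features, X = self._fitted()
        table = predict_variants(model, features)
        assert np.allclose(
            table["predicted_activity_raw"].to_numpy(), model.fitted
        )

    def test_negative_prediction_clipped_raw_retained(self):
        model, features, X = self._fitted()
        features.values.loc["RAG1:A1V", ["s1", "s2"]] = [-2.0, 3.0]  # push < 0
        table = predict_variants(model, features)
        row = table.loc["RAG1:A1V"]
        assert row["predicted_activity_raw"] < 0
        assert row["predicted_activity"] == 0.0
        assert row["activity_group"] == "AG1"

    def test_missing_feature_flags_unpredictable(self):
        model, features, X = self._fitted()
        features.values.loc["RAG1:A2V", "s2"] = np.nan
        table = predict_variants(model, features)
        assert not table.loc["RAG1:A2V", "predictable"]
        assert np.isnan(table.loc["RAG1:A2V", "predicted_activity_raw"])
        assert table["predictable"].sum() == 39

    def test_pure_function_repeated_runs_identical(self):
        model, features, X = self._fitted()
        a = predict_variants(model, features, model_id="m1")
        b = predict_variants(model, features, model_id="m1")
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_empty_predictable_set_rejected(self):
        model, features, X = self._fitted()
        features.values["s1"] = np.nan
        with pytest.raises(ValueError, match="complete feature set"):
            predict_variants(model, features)


class TestAnnotateLocation:
    def _complex(self):
        # chain A: RAG1 10-residue strand; chain C: RAG2 near residue 5;
        # chain E: DNA near residue 1; residues 8..10 isolated tail
        ids, xyz = [], []
        for i in range(10):
            ids.append(("A", i + 1))
            xyz.append([4.0 * i, 0.0, 0.0])
        ids += [("C", 1), ("C", 2)]
        xyz += [[16.0, 5.0, 0.0], [20.0, 5.0, 0.0]]
        ids += [("E", 1)]
        xyz += [[0.0, 3.0, 0.0]]
        # densify around residue 3 so it counts as buried
        for j in range(20):
            ids.append(("A", 100 + j))
            xyz.append([8.0 + 2.0 * np.cos(j), 2.0 * np.sin(j), 1.0 + 0.1 * j])
        model = CalphaModel(tuple(ids), np.asarray(xyz, float))
        roles = {"RAG1": ("A",), "RAG2": ("C",), "DNA": ("E",)}
        return model, roles

    def test_precedence_near_dna_over_interface(self):
        model, roles = self._complex()
        # residue 1 is 3 Å from DNA; also give it a nearby RAG2 site
        cats = annotate_location([("RAG1", 1)], model, roles)
        assert cats == ["near_DNA"]

    def test_interface_and_surface_and_buried(self):
        model, roles = self._complex()
        cats = annotate_location(
            [("RAG1", 5), ("RAG1", 10), ("RAG1", 3)], model, roles
        )
        assert cats[0] == "interface"  # 4 Å from a RAG2 site (beyond DNA cutoff)
        assert cats[1] == "surface"  # isolated tail, few neighbors
        assert cats[2] == "buried"  # surrounded by the dense cluster

    def test_unmapped_residue(self):
        model, roles = self._complex()
        assert annotate_location([("RAG1", 999)], model, roles) == ["unmapped"]

    def test_partition_every_mapped_residue_one_category(self):
        model, roles = self._complex()
        residues = [("RAG1", i + 1) for i in range(10)]
        cats = annotate_location(residues, model, roles)
        assert set(cats) <= {"near_DNA", "interface", "surface", "buried"}
        assert len(cats) == 10
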