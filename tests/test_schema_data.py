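"""Schema validation, delimited-text I/O, preprocessing and fold construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ttsurv.data import (SurvivalDataset, apply_preprocessor, fit_preprocessor,
                         load_dataset, stratified_kfold, write_dataset)
from ttsurv.schema import Feature, FeatureSchema


def write_csv(tmp_path, rows, header="id,age,stage,sex,duration_days,event"):
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestSchema:
    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Feature("stage", "categorical", ("I", "I"))

    def test_schema_needs_a_categorical_feature(self):
        with pytest.raises(ValueError, match="categorical"):
            FeatureSchema((Feature("age", "continuous"),))

    def test_outcome_columns_cannot_be_features(self):
        with pytest.raises(ValueError):
            FeatureSchema((Feature("event", "categorical", ("0", "1")),),
                          duration_column="t", event_column="event")

    def test_stage_restriction_is_nested(self, tiny_schema):
        on = FeatureSchema(
            tiny_schema.features + (
                Feature("deauville", "categorical", tuple("12345"),
                        "on-treatment"),))
        pre_names = {f.name for f in on.restrict_to_stage("pretreatment").features}
        on_names = {f.name for f in on.restrict_to_stage("on-treatment").features}
        assert pre_names < on_names and "deauville" not in pre_names

    def test_yaml_round_trip(self, tiny_schema, tmp_path):
        tiny_schema.to_yaml(tmp_path / "s.yaml")
        assert FeatureSchema.from_yaml(tmp_path / "s.yaml") == tiny_schema


class TestLoadDataset:
    def test_three_row_file_maps_directly(self, tiny_schema, tmp_path):
        path = write_csv(tmp_path, ["a,50,I,F,100,1", "b,60,IV,M,200,0",
                                    "c,70,II,F,300.5,1"])
        ds = load_dataset(path, tiny_schema)
        assert ds.n == 3
        assert list(ds.ids) == ["a", "b", "c"]
        np.testing.assert_array_equal(ds.x_cat, [[0, 0], [3, 1], [1, 0]])
        np.testing.assert_allclose(ds.t, [100, 200, 300.5])

    def test_unknown_level_names_feature_row_and_label(self, tiny_schema, tmp_path):
        path = write_csv(tmp_path, ["a,50,I,F,100,1", "b,60,V,M,200,0"])
        with pytest.raises(ValueError, match=r"'V'.*'stage'.*row 1"):
            load_dataset(path, tiny_schema)

    def test_nonpositive_duration_rejected(self, tiny_schema, tmp_path):
        path = write_csv(tmp_path, ["a,50,I,F,0,1"])
        with pytest.raises(ValueError, match="duration"):
            load_dataset(path, tiny_schema)

    def test_event_outside_binary_rejected(self, tiny_schema, tmp_path):
        path = write_csv(tmp_path, ["a,50,I,F,10,2"])
        with pytest.raises(ValueError, match="event"):
            load_dataset(path, tiny_schema)

    def test_missing_value_rejected_not_imputed(self, tiny_schema, tmp_path):
        path = write_csv(tmp_path, ["a,,I,F,10,1"])
        with pytest.raises(ValueError, match="missing"):
            load_dataset(path, tiny_schema)

    def test_write_load_round_trip(self, tiny_data, tmp_path):
        write_dataset(tiny_data, tmp_path / "out.csv")
        back = load_dataset(tmp_path / "out.csv", tiny_data.schema)
        np.testing.assert_allclose(back.x_cont, tiny_data.x_cont)
        np.testing.assert_array_equal(back.x_cat, tiny_data.x_cat)
        np.testing.assert_allclose(back.t, tiny_data.t)
        np.testing.assert_array_equal(back.d, tiny_data.d)
        np.testing.assert_array_equal(back.ids, tiny_data.ids)


def make_cont_dataset(schema, values):
    n = len(values)
    return SurvivalDataset(schema, np.asarray(values, float).reshape(n, 1),
                           np.zeros((n, 2), dtype=int), np.ones(n),
                           np.ones(n, dtype=int), np.arange(n))


class TestPreprocessor:
    def test_two_point_column(self, tiny_schema):
        pre = fit_preprocessor(make_cont_dataset(tiny_schema, [0, 10]), tiny_schema)
        np.testing.assert_allclose(pre.location, [5.0])
        np.testing.assert_allclose(pre.scale, [5.0])

    def test_population_standard_deviation(self, tiny_schema):
        pre = fit_preprocessor(make_cont_dataset(tiny_schema, [1, 2, 3]),
                               tiny_schema)
        np.testing.assert_allclose(pre.location, [2.0])
        np.testing.assert_allclose(pre.scale, [np.sqrt(2.0 / 3.0)], rtol=1e-12)

    def test_constant_column_is_an_error(self, tiny_schema):
        with pytest.raises(ValueError, match="constant"):
            fit_preprocessor(make_cont_dataset(tiny_schema, [4, 4, 4]), tiny_schema)

    def test_transform_of_training_data_is_standardised(self, tiny_data):
        pre = fit_preprocessor(tiny_data, tiny_data.schema)
        out = apply_preprocessor(pre, tiny_data)
        np.testing.assert_allclose(out.x_cont.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.x_cont.std(axis=0), 1.0, rtol=1e-12)

    def test_categorical_codes_untouched(self, tiny_data):
        pre = fit_preprocessor(tiny_data, tiny_data.schema)
        out = apply_preprocessor(pre, tiny_data)
        assert out.x_cat.tobytes() == tiny_data.x_cat.tobytes()

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_transform_is_affine_equivariant(self, a, b):
        # standardising a*x + b gives the same z-scores as standardising x
        schema = FeatureSchema((Feature("age", "continuous"),
                                Feature("stage", "categorical", ("I", "II")),
                                Feature("sex", "categorical", ("F", "M"))))
        x = np.array([1.0, 4.0, 9.0, 16.0])
        base = make_cont_dataset(schema, x)
        scaled = make_cont_dataset(schema, a * x + b)
        z0 = apply_preprocessor(fit_preprocessor(base, schema), base)
        z1 = apply_preprocessor(fit_preprocessor(scaled, schema), scaled)
        np.testing.assert_allclose(z0.x_cont, z1.x_cont, atol=1e-9)


class TestStratifiedKFold:
    @staticmethod
    def dataset(n, events, schema):
        d = np.zeros(n, dtype=int)
        d[:events] = 1
        return SurvivalDataset(schema, np.zeros((n, 1)),
                               np.zeros((n, 2), dtype=int),
                               np.arange(1, n + 1, dtype=float), d, np.arange(n))

    def test_event_counts_balanced(self, tiny_schema):
        ds = self.dataset(10, 4, tiny_schema)
        for tr, va in stratified_kfold(ds, 2, seed=0):
            assert ds.d[va].sum() == 2 and (ds.d[va] == 0).sum() == 3

    def test_folds_partition_indices(self, tiny_schema):
        ds = self.dataset(23, 9, tiny_schema)
        folds = stratified_kfold(ds, 4, seed=1)
        validation = np.concatenate([va for _, va in folds])
        assert sorted(validation) == list(range(23))
        counts = np.zeros(23, int)
        for tr, _ in folds:
            counts[tr] += 1
        assert np.all(counts == 3)  # every index in exactly k-1 training sets

    def test_deterministic_given_seed(self, tiny_schema):
        ds = self.dataset(20, 8, tiny_schema)
        a = stratified_kfold(ds, 5, seed=42)
        b = stratified_kfold(ds, 5, seed=42)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_small_stratum_is_an_error(self, tiny_schema):
        ds = self.dataset(10, 2, tiny_schema)
        with pytest.raises(ValueError, match="stratum"):
            stratified_kfold(ds, 3, seed=0)
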