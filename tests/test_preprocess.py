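import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bold.preprocess import (
    FeatureTable,
    NormalizationParams,
    PreprocessError,
    SplitSpec,
    clean,
    kfold_indices,
    min_max_apply,
    min_max_fit_transform,
    stratified_split,
)


def table(values, outcome, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"c{i}" for i in range(values.shape[1])]
    return FeatureTable(names, values, outcome)


class TestFeatureTable:
    def test_invariants_enforced(self):
        with pytest.raises(PreprocessError):
            table([[1.0], [2.0]], [0, 2])
        with pytest.raises(PreprocessError):
            table([[1.0]], [0, 1])

    def test_csv_round_trip(self, tmp_path, small_table):
        path = tmp_path / "t.csv"
        small_table.to_csv(path)
        back = FeatureTable.from_csv(path)
        assert back.attribute_names == small_table.attribute_names
        np.testing.assert_allclose(back.values, small_table.values)
        np.testing.assert_array_equal(back.outcome, small_table.outcome)

    def test_csv_missing_markers_become_nan(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("a,b,Outcome\n1,2,0\n,NA,1\n3,4,1\n")
        t = FeatureTable.from_csv(path)
        assert np.isnan(t.values[1]).all()


class TestClean:
    def test_duplicate_rows_collapse(self):
        t = table([[1.0, 2.0], [1.0, 2.0]], [1, 1])
        with pytest.raises(PreprocessError):
            # both attributes become constant once deduplicated to one row
            clean(t)
        t = table([[1.0, 2.0], [1.0, 2.0], [3.0, 5.0]], [1, 1, 0])
        cleaned, report = clean(t)
        assert cleaned.n_rows == 2
        assert report.duplicate_rows_removed == 1

    def test_constant_attribute_dropped(self):
        t = table([[3.0, 1.0], [3.0, 2.0], [3.0, 4.0]], [0, 1, 0])
        cleaned, report = clean(t)
        assert report.attributes_removed == ["c0"]
        assert cleaned.attribute_names == ["c1"]

    def test_missing_row_dropped_by_default(self):
        vals = np.arange(10.0).reshape(5, 2)
        vals[2, 0] = np.nan
        cleaned, report = clean(table(vals, [0, 1, 0, 1, 0], ["Glucose", "BMI"]))
        assert cleaned.n_rows == 4
        assert report.rows_removed_missing == 1

    def test_median_imputation_option(self):
        vals = np.arange(10.0).reshape(5, 2)
        vals[2, 0] = np.nan
        cleaned, report = clean(
            table(vals, [0, 1, 0, 1, 0]), missing_policy="median"
        )
        assert cleaned.n_rows == 5
        assert report.values_imputed == 1
        # median of remaining c0 entries {0, 2, 6, 8}
        assert cleaned.values[2, 0] == 4.0

    def test_zeros_as_missing_opt_in(self):
        vals = np.array([[0.0, 1.0], [5.0, 2.0], [6.0, 3.0], [7.0, 4.0]])
        cleaned, _ = clean(
            table(vals, [0, 1, 0, 1], ["Glucose", "BMI"]),
            missing_policy="median",
            zeros_as_missing=["Glucose"],
        )
        assert cleaned.values[0, 0] == 6.0  # median of {5, 6, 7}

    def test_unusable_dataset_errors(self):
        vals = np.full((3, 1), np.nan)
        with pytest.raises(PreprocessError):
            clean(table(vals, [0, 1, 0]))


class TestMinMax:
    def test_endpoints_map_to_unit_interval(self):
        t = table(np.array([[0.0], [5.0], [10.0]]), [0, 1, 0])
        norm, params = min_max_fit_transform(t)
        np.testing.assert_allclose(norm.values.ravel(), [0.0, 0.5, 1.0])
        assert norm.values.min() == 0.0 and norm.values.max() == 1.0

    def test_published_glucose_bounds(self):
        # (120.9 - 0) / (198 - 0)
        params = NormalizationParams(["Glucose"], [0.0], [198.0])
        t = table(np.array([[120.9]]), [1], ["Glucose"])
        out = min_max_apply(t, params)
        assert out.values[0, 0] == pytest.approx(0.61061, abs=5e-6)

    def test_apply_matches_fit_and_half_point(self):
        t = table(np.array([[0.0], [99.0], [198.0]]), [0, 1, 0], ["Glucose"])
        norm, params = min_max_fit_transform(t)
        again = min_max_apply(t, params)
        np.testing.assert_array_equal(norm.values, again.values)
        assert again.values[1, 0] == 0.5

    def test_extrapolation_flagged_not_clipped(self):
        params = NormalizationParams(["x"], [10.0], [20.0])
        t = table(np.array([[5.0]]), [0], ["x"])
        with pytest.warns(UserWarning):
            out = min_max_apply(t, params)
        assert out.values[0, 0] == -0.5

    def test_degenerate_params_error(self):
        params = NormalizationParams(["x"], [2.0], [2.0])
        with pytest.raises(PreprocessError):
            min_max_apply(table(np.array([[2.0]]), [0], ["x"]), params)

    def test_constant_attribute_errors_at_fit(self):
        with pytest.raises(PreprocessError):
            min_max_fit_transform(table(np.array([[1.0], [1.0]]), [0, 1]))

    def test_name_mismatch_errors(self):
        params = NormalizationParams(["x"], [0.0], [1.0])
        with pytest.raises(PreprocessError):
            min_max_apply(table(np.array([[0.5]]), [0], ["y"]), params)

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_recovers_values(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 50, size=(20, 3))
        t = table(vals, rng.integers(0, 2, 20))
        norm, params = min_max_fit_transform(t)
        back = params.invert(norm)
        np.testing.assert_allclose(back.values, vals, rtol=1e-9, atol=1e-9)

    def test_params_json_round_trip(self):
        params = NormalizationParams(["a", "b"], [0.0, -1.0], [2.0, 3.5])
        back = NormalizationParams.from_json(params.to_json())
        assert back.attribute_names == ["a", "b"]
        np.testing.assert_array_equal(back.observed_max, params.observed_max)


class TestStratifiedSplit:
    def test_exact_allocation(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(35, dtype=int), np.zeros(65, dtype=int)]
        t = table(rng.random((100, 2)), y)
        train, test = stratified_split(t, SplitSpec(0.8, 2, seed=5))
        assert train.n_rows == 80 and test.n_rows == 20
        assert train.outcome.sum() == 28 and test.outcome.sum() == 7

    def test_partition_and_determinism(self, small_table):
        spec = SplitSpec(0.75, 2, seed=11)
        tr1, te1 = stratified_split(small_table, spec)
        tr2, te2 = stratified_split(small_table, spec)
        np.testing.assert_array_equal(tr1.values, tr2.values)
        np.testing.assert_array_equal(te1.values, te2.values)
        merged = np.vstack([tr1.values, te1.values])
        original = small_table.values
        assert sorted(map(tuple, merged)) == sorted(map(tuple, original))

    def test_degenerate_fraction_errors(self):
        rng = np.random.default_rng(0)
        t = table(rng.random((10, 2)), [0, 1] * 5)
        with pytest.raises(PreprocessError):
            stratified_split(t, SplitSpec(0.999, 2, seed=0))

    def test_single_class_errors(self):
        t = table(np.random.default_rng(0).random((6, 2)), [1] * 6)
        with pytest.raises(PreprocessError):
            stratified_split(t, SplitSpec(0.8, 2, seed=0))


class TestKFold:
    def test_equal_division(self):
        rng = np.random.default_rng(4)
        t = table(rng.random((20, 2)), [0, 1] * 10)
        folds = kfold_indices(t, SplitSpec(0.8, 10, seed=0))
        assert [len(va) for _, va in folds] == [2] * 10

    def test_remainder_allocation(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(13, dtype=int), np.zeros(10, dtype=int)]
        t = table(rng.random((23, 2)), y)
        sizes = sorted(len(va) for _, va in kfold_indices(t, SplitSpec(0.8, 10, seed=0)))
        assert sizes == [2] * 7 + [3] * 3

    def test_partition_property(self, small_table):
        folds = kfold_indices(small_table, SplitSpec(0.8, 5, seed=9))
        all_val = np.concatenate([va for _, va in folds])
        assert len(all_val) == len(set(all_val.tolist())) == small_table.n_rows
        for tr, va in folds:
            assert set(tr) & set(va) == set()
            assert len(tr) + len(va) == small_table.n_rows

    def test_too_many_folds_errors(self, small_table):
        with pytest.raises(PreprocessError):
            kfold_indices(small_table, SplitSpec(0.8, 61, seed=0))
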