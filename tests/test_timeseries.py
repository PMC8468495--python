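import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthfair import (
    CategoryLevel,
    DatasetSchema,
    SubgroupDefinition,
    TabularDataset,
    aggregate_series,
    categorize,
    directional_symmetry,
    enumerate_subgroups,
    evaluate_timeseries,
    make_pair,
    pcc_mapped,
    ts_log_disparity,
)
from synthfair.errors import EmptySubgroupError, UndefinedResemblanceError

finite_floats = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


@pytest.fixture
def three_point_schema():
    return DatasetSchema(
        protected_attrs=(("gender", ("M", "F")),),
        temporal_features=(("x", ("t0", "t1", "t2")),),
    )


def make_ds(schema, gender, series_rows, role="real"):
    cols = schema.columns_of("x")
    data = {"gender": gender}
    arr = np.asarray(series_rows, dtype=float)
    for j, c in enumerate(cols):
        data[c] = arr[:, j]
    return TabularDataset(role, pd.DataFrame(data), schema)


class TestAggregation:
    def test_identical_rows_mean_is_the_row(self, three_point_schema):
        ds = make_ds(three_point_schema, ["M", "M"], [[1, 4, 2], [1, 4, 2]])
        sg = SubgroupDefinition.from_mapping({"gender": "M"}, three_point_schema)
        out = aggregate_series(ds, sg, "mean")
        np.testing.assert_allclose(out["x"], [1, 4, 2])

    def test_mean_of_opposed_rows(self, three_point_schema):
        ds = make_ds(three_point_schema, ["M", "M"], [[1, 2, 3], [3, 2, 1]])
        sg = SubgroupDefinition.from_mapping({"gender": "M"}, three_point_schema)
        np.testing.assert_allclose(aggregate_series(ds, sg, "mean")["x"], [2, 2, 2])

    def test_sum_and_count_statistics(self, three_point_schema):
        ds = make_ds(three_point_schema, ["M", "M", "F"], [[1, 0, 3], [1, 2, 0], [9, 9, 9]])
        sg = SubgroupDefinition.from_mapping({"gender": "M"}, three_point_schema)
        np.testing.assert_allclose(aggregate_series(ds, sg, "sum")["x"], [2, 2, 3])
        # count counts rows with a nonzero value per time point
        np.testing.assert_allclose(aggregate_series(ds, sg, "count")["x"], [2, 1, 1])

    def test_complement_aggregation(self, three_point_schema):
        ds = make_ds(three_point_schema, ["M", "F"], [[1, 2, 3], [5, 5, 5]])
        sg = SubgroupDefinition.from_mapping({"gender": "M"}, three_point_schema)
        np.testing.assert_allclose(
            aggregate_series(ds, sg, "mean", complement=True)["x"], [5, 5, 5]
        )

    def test_empty_subgroup_raises(self, three_point_schema):
        ds = make_ds(three_point_schema, ["F"], [[1, 2, 3]])
        sg = SubgroupDefinition.from_mapping({"gender": "M"}, three_point_schema)
        with pytest.raises(EmptySubgroupError):
            aggregate_series(ds, sg, "mean")


class TestPccMapped:
    def test_perfect_correlation(self):
        assert pcc_mapped([1, 2, 5], [1, 2, 5]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pcc_mapped([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_computed_half_correlation(self):
        assert pcc_mapped([1, 2, 3], [1, 3, 2]) == pytest.approx(0.75, rel=1e-12)

    @pytest.mark.parametrize("a,b,reason", [
        ([1, 1, 1], [1, 2, 3], "zero_variance_real"),
        ([1, 2, 3], [4, 4, 4], "zero_variance_synthetic"),
    ])
    def test_constant_series_undefined(self, a, b, reason):
        with pytest.raises(UndefinedResemblanceError) as exc:
            pcc_mapped(a, b)
        assert exc.value.reason == reason

    @given(
        shift=st.floats(min_value=-100, max_value=100, allow_nan=False),
        scale=st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, shift, scale):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        b = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        base = pcc_mapped(a, b)
        assert pcc_mapped(a * scale + shift, b) == pytest.approx(base, abs=1e-9)

    def test_symmetry(self):
        a, b = [1.0, 4.0, 2.0, 8.0], [2.0, 3.0, 1.0, 9.0]
        assert pcc_mapped(a, b) == pcc_mapped(b, a)


class TestDirectionalSymmetry:
    def test_identical_monotone_series(self):
        assert directional_symmetry([1, 2, 3, 4], [1, 2, 3, 4]) == 100.0

    def test_hand_enumerated_example(self):
        # signs (+,+,-) vs (+,-,-): 2 of 3 steps agree
        assert directional_symmetry([1, 2, 3, 2], [1, 3, 2, 1]) == pytest.approx(200 / 3)

    def test_tie_counts_as_agreement(self):
        assert directional_symmetry([1, 1], [1, 2]) == 100.0

    def test_complete_disagreement(self):
        assert directional_symmetry([1, 2, 3], [3, 2, 1]) == 0.0

    @given(
        shift=st.floats(min_value=-50, max_value=50, allow_nan=False),
        scale=st.floats(min_value=0.01, max_value=50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_and_positive_scale_invariance(self, shift, scale):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        b = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        base = directional_symmetry(a, b)
        assert directional_symmetry(a * scale + shift, b) == pytest.approx(base)

    def test_symmetry(self):
        a, b = [1.0, 4.0, 2.0], [2.0, 3.0, 1.0]
        assert directional_symmetry(a, b) == directional_symmetry(b, a)

    def test_too_short(self):
        with pytest.raises(ValueError):
            directional_symmetry([1], [2])


class TestTsLogDisparity:
    def test_equal_resemblance_is_zero(self):
        assert ts_log_disparity(0.8, 0.8) == 0.0

    def test_adequate_example(self):
        ld = ts_log_disparity(0.90, 0.95)
        assert ld == pytest.approx(-0.054067, abs=1e-6)
        assert categorize(ld) is CategoryLevel.ADEQUATE

    def test_highly_under_example(self):
        ld = ts_log_disparity(0.70, 0.95)
        assert ld == pytest.approx(-0.305382, abs=1e-6)
        assert categorize(ld) is CategoryLevel.HIGHLY_UNDER

    def test_antisymmetry(self):
        assert ts_log_disparity(0.7, 0.9) == pytest.approx(-ts_log_disparity(0.9, 0.7))

    def test_scale_factor_cancels(self):
        # DS values on the 0-100 scale give the same disparity as 0-1 values
        assert ts_log_disparity(70.0, 95.0) == pytest.approx(ts_log_disparity(0.70, 0.95))

    def test_zero_resemblance_raises(self):
        with pytest.raises(UndefinedResemblanceError):
            ts_log_disparity(0.0, 0.9)


class TestEvaluateTimeseries:
    def _pair(self, schema, real_rows, synth_rows, real_gender, synth_gender):
        real = make_ds(schema, real_gender, real_rows, "real")
        synth = make_ds(schema, synth_gender, synth_rows, "synthetic")
        return make_pair(real, synth, schema)

    def test_identity_pair_zero_disparity(self, three_point_schema):
        rows = [[1, 2, 3], [2, 1, 3], [3, 2, 1], [1, 3, 2]]
        gender = ["M", "M", "F", "F"]
        pair = self._pair(three_point_schema, rows, rows, gender, gender)
        sgs = enumerate_subgroups(three_point_schema, "all")
        for metric in ("pcc", "ds"):
            for r in evaluate_timeseries(pair, sgs, metric=metric):
                assert r.ts_log_disparity == pytest.approx(0.0)
                assert r.category is CategoryLevel.ADEQUATE

    def test_missing_subgroup_reported_missing(self, three_point_schema):
        pair = self._pair(
            three_point_schema,
            [[1, 2, 3], [3, 1, 2]],
            [[1, 2, 3], [3, 1, 2]],
            ["M", "F"],
            ["F", "F"],
        )
        sgs = enumerate_subgroups(three_point_schema, "all")
        res = {r.subgroup.label(): r for r in evaluate_timeseries(pair, sgs)}
        assert res["gender=M"].category is CategoryLevel.MISSING
        assert "missing_in_synthetic" in res["gender=M"].flags

    def test_constant_series_flagged_not_fatal(self, three_point_schema):
        pair = self._pair(
            three_point_schema,
            [[5, 5, 5], [1, 2, 3]],
            [[5, 5, 5], [1, 2, 3]],
            ["M", "F"],
            ["M", "F"],
        )
        sgs = enumerate_subgroups(three_point_schema, "all")
        res = {r.subgroup.label(): r for r in evaluate_timeseries(pair, sgs, metric="pcc")}
        assert res["gender=M"].res_g1 is None
        assert any("zero_variance" in f for f in res["gender=M"].flags)
        # the non-constant subgroup keeps its own resemblance; its disparity
        # is undefined because its complement is the constant series
        assert res["gender=F"].res_g1 == pytest.approx(1.0)
        assert res["gender=F"].ts_log_disparity is None
        assert "undefined_resemblance" in res["gender=F"].flags

    def test_metrics_can_disagree_in_category(self):
        # crafted series: strong linear trend (high PCC) whose micro-steps
        # alternate against the real series (low DS)
        k = np.arange(10, dtype=float)
        real_series = k
        zigzag = k + np.where(k % 2 == 0, 0.6, -0.6)
        assert pcc_mapped(real_series, zigzag) > 0.95
        assert directional_symmetry(real_series, zigzag) <= 50.0
        # subgroup uses the zigzag synthetic series, complement a faithful copy
        pcc_cat = categorize(ts_log_disparity(pcc_mapped(real_series, zigzag), 1.0))
        ds_cat = categorize(
            ts_log_disparity(
                directional_symmetry(real_series, zigzag),
                directional_symmetry(real_series, real_series),
            )
        )
        assert pcc_cat is CategoryLevel.ADEQUATE
        assert ds_cat is CategoryLevel.HIGHLY_UNDER

    def test_per_feature_layout_on_multivariate_panel(self, asd_schema):
        from synthfair.simulate import generate_temporal_pair, preset_spec

        schema, spec = preset_spec("asd", n_real=400, n_synthetic=400, seed=2)
        pair = generate_temporal_pair(schema, spec)
        sgs = enumerate_subgroups(schema, 1)
        results = evaluate_timeseries(pair, sgs, metric="pcc", mode="per_feature")
        evaluated = [r for r in results if r.per_feature is not None]
        assert evaluated, "expected at least one evaluable subgroup"
        for r in evaluated:
            assert set(r.per_feature) == set(schema.feature_names)
            assert len(r.per_feature) == 7
            vals = [v[0] for v in r.per_feature.values() if v[0] is not None]
            assert r.res_g1 == pytest.approx(np.mean(vals))

    def test_concatenated_mode_joins_features_in_schema_order(self):
        schema = DatasetSchema(
            protected_attrs=(("gender", ("M", "F")),),
            temporal_features=(("a", ("a0", "a1")), ("b", ("b0", "b1"))),
        )
        df = pd.DataFrame(
            {
                "gender": ["M", "F"],
                "a0": [1.0, 5.0],
                "a1": [2.0, 6.0],
                "b0": [9.0, 7.0],
                "b1": [4.0, 8.0],
            }
        )
        real = TabularDataset("real", df, schema)
        synth = TabularDataset("synthetic", df.copy(), schema)
        pair = make_pair(real, synth, schema)
        sgs = enumerate_subgroups(schema, 1)
        results = evaluate_timeseries(pair, sgs, metric="pcc", mode="concatenated")
        for r in results:
            assert r.per_feature is None
            assert r.res_g1 == pytest.approx(1.0)
            assert r.ts_log_disparity == pytest.approx(0.0)

    def test_invalid_mode_and_empty_subgroups(self, three_point_schema):
        pair = self._pair(
            three_point_schema, [[1, 2, 3]], [[1, 2, 3]], ["M"], ["M"]
        )
        with pytest.raises(ValueError):
            evaluate_timeseries(pair, [], metric="pcc")
        sgs = enumerate_subgroups(three_point_schema, "all")
        with pytest.raises(ValueError):
            evaluate_timeseries(pair, sgs, mode="bogus")
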