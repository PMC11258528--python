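"""Outcome construction, splitting, filtering, binning, encoding, scaling."""

import numpy as np
import pandas as pd
import pytest

import bnscreen as b
from bnscreen.dataset import ColumnMeta, SurveyDataset
from bnscreen.prep import decode


def make_dataset(frame: pd.DataFrame, roles=None, dtypes=None) -> SurveyDataset:
    roles = roles or {}
    dtypes = dtypes or {}
    meta = {
        c: ColumnMeta(c, roles.get(c, "feature"), dtypes.get(c, "ordinal"))
        for c in frame.columns
    }
    return SurveyDataset(frame, meta)


class TestComputeOutcome:
    def test_cutoff_boundary(self):
        assert b.compute_outcome([1, 1, 1, 1, 1, 1, 1, 1, 2], age=40) == 1
        assert b.compute_outcome([1, 1, 1, 1, 1, 1, 1, 1, 1], age=40) == 0

    def test_all_zero_items(self):
        assert b.compute_outcome([0] * 9, age=40) == 0

    def test_incomplete_items_excluded(self):
        assert b.compute_outcome([1, 1, 1, 1, 1, 1, 1, 1, None], age=40) is None

    def test_minor_excluded(self):
        assert b.compute_outcome([3] * 9, age=17) is None
        assert b.compute_outcome([3] * 9, age=18) == 1

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValueError):
            b.compute_outcome([4] + [0] * 8, age=40)


class TestSplit:
    def test_floor_rule_and_partition(self):
        d = make_dataset(pd.DataFrame({"x": range(10)}))
        cfg = b.PrepConfig(seed=1)
        tr, te = b.split_train_test(d, cfg)
        assert (tr.n, te.n) == (7, 3)
        assert set(tr.frame["x"]) | set(te.frame["x"]) == set(range(10))
        assert set(tr.frame["x"]) & set(te.frame["x"]) == set()

    def test_same_seed_same_partition(self):
        d = make_dataset(pd.DataFrame({"x": range(100)}))
        cfg = b.PrepConfig(seed=7)
        tr1, _ = b.split_train_test(d, cfg)
        tr2, _ = b.split_train_test(d, cfg)
        assert list(tr1.frame["x"]) == list(tr2.frame["x"])

    def test_exact_floor_at_scale(self):
        d = make_dataset(pd.DataFrame({"x": range(100003)}))
        tr, te = b.split_train_test(d, b.PrepConfig(seed=0))
        assert tr.n == int(np.floor(100003 * 0.7))
        assert tr.n + te.n == 100003


class TestFilters:
    def test_missing_fraction_strictness(self):
        frame = pd.DataFrame(
            {
                "drop21": [np.nan] * 21 + [1.0, 2.0] * 39 + [1.0],
                "keep20": [np.nan] * 20 + [1.0, 2.0] * 40,
                "ok": [1.0, 2.0] * 50,
            }
        )
        out, report = b.filter_columns_and_rows(make_dataset(frame), b.PrepConfig())
        dropped = {d["name"]: d["rule"] for d in report["columns"]}
        assert dropped == {"drop21": "missing_fraction"}
        assert "keep20" in out.frame.columns

    def test_constant_column_dropped(self):
        frame = pd.DataFrame({"const": [5.0] * 10, "ok": [1.0, 2.0] * 5})
        out, report = b.filter_columns_and_rows(make_dataset(frame), b.PrepConfig())
        assert {d["name"] for d in report["columns"]} == {"const"}
        assert [d["rule"] for d in report["columns"]] == ["single_level"]

    def test_depression_columns_dropped_first(self):
        frame = pd.DataFrame({"dep": [0.0, 1.0] * 5, "ok": [1.0, 2.0] * 5})
        ds = make_dataset(frame, roles={"dep": "depression_related"})
        out, report = b.filter_columns_and_rows(ds, b.PrepConfig())
        assert report["columns"][0] == {"name": "dep", "rule": "depression_related"}
        assert "dep" not in out.frame.columns

    def test_row_filter_over_remaining_columns(self):
        frame = pd.DataFrame(
            {
                "a": [np.nan] + [1.0, 2.0] * 5,
                "b": [np.nan] + [2.0, 1.0] * 5,
                "c": [np.nan] + [1.0, 2.0] * 5,
                "d": [1.0, 2.0] * 5 + [1.0],
            }
        )
        # columns are each 1/11 missing (kept); row 0 is 75% missing (dropped)
        out, report = b.filter_columns_and_rows(make_dataset(frame), b.PrepConfig())
        assert not report["columns"]
        assert report["rows_dropped"] == 1
        assert out.n == 10

    def test_report_is_exhaustive(self):
        frame = pd.DataFrame(
            {
                "dep": [0.0, 1.0] * 5,
                "const": [3.0] * 10,
                "ok": [1.0, 2.0] * 5,
            }
        )
        ds = make_dataset(frame, roles={"dep": "depression_related"})
        out, report = b.filter_columns_and_rows(ds, b.PrepConfig())
        dropped = {d["name"] for d in report["columns"]}
        assert dropped | set(report["retained_columns"]) == set(report["original_columns"])

    def test_all_columns_dropped_is_error(self):
        frame = pd.DataFrame({"const": [1.0] * 4})
        with pytest.raises(ValueError, match="dropped"):
            b.filter_columns_and_rows(make_dataset(frame), b.PrepConfig())


class TestBinning:
    def test_uniform_quartiles_balanced(self):
        vals = np.tile(np.arange(40, dtype=float), 100)  # 40 distinct, n=4000
        ds = make_dataset(pd.DataFrame({"x": vals}), dtypes={"x": "numeric"})
        out, edges = b.bin_high_cardinality(ds, b.PrepConfig())
        counts = out.frame["x"].value_counts()
        assert sorted(counts.index) == [1.0, 2.0, 3.0, 4.0]
        assert all(abs(c - 1000) <= 1 for c in counts)

    def test_boundary_30_levels_untouched(self):
        vals = np.tile(np.arange(30, dtype=float), 10)
        ds = make_dataset(pd.DataFrame({"x": vals}), dtypes={"x": "numeric"})
        out, edges = b.bin_high_cardinality(ds, b.PrepConfig())
        assert edges == {}
        assert out.frame["x"].nunique() == 30

    def test_training_edges_reused_on_test(self):
        rng = np.random.default_rng(0)
        train = make_dataset(pd.DataFrame({"x": rng.uniform(0, 100, 500)}), dtypes={"x": "numeric"})
        test = make_dataset(pd.DataFrame({"x": rng.uniform(0, 100, 500)}), dtypes={"x": "numeric"})
        _, edges = b.bin_high_cardinality(train, b.PrepConfig())
        out, _ = b.bin_high_cardinality(test, b.PrepConfig(), edges=edges)
        assert set(out.frame["x"].unique()) <= {1.0, 2.0, 3.0, 4.0}


class TestEncoding:
    def test_missing_class_and_order(self):
        frame = pd.DataFrame({"q": ["No", "Yes", None, "No"]})
        ds = SurveyDataset(frame, {"q": ColumnMeta("q", "feature", "binary", ["No", "Yes"])})
        out, maps = b.encode_and_impute(ds, b.PrepConfig())
        assert maps["q"] == {"No": 1, "Yes": 2}
        assert out.frame["q"].tolist() == [1, 2, 0, 1]

    def test_raw_zero_shifts_up(self):
        """A raw value of 0 never collides with the missing code."""
        frame = pd.DataFrame({"q": [0.0, 1.0, 2.0, np.nan]})
        out, maps = b.encode_and_impute(make_dataset(frame), b.PrepConfig())
        assert maps["q"] == {0.0: 1, 1.0: 2, 2.0: 3}
        assert out.frame["q"].tolist() == [1, 2, 3, 0]

    def test_no_missing_leaves_code_zero_unused(self):
        frame = pd.DataFrame({"q": [1.0, 2.0, 1.0]})
        out, _ = b.encode_and_impute(make_dataset(frame), b.PrepConfig())
        assert out.frame["q"].min() == 1

    def test_round_trip(self):
        frame = pd.DataFrame({"q": [3.0, 7.0, 5.0, np.nan, 7.0]})
        ds = make_dataset(frame)
        out, maps = b.encode_and_impute(ds, b.PrepConfig())
        back = decode(out, maps)
        assert back.frame["q"].tolist()[:3] == [3.0, 7.0, 5.0]

    def test_unseen_level_maps_to_missing(self):
        train = make_dataset(pd.DataFrame({"q": [1.0, 2.0]}))
        _, maps = b.encode_and_impute(train, b.PrepConfig())
        test = make_dataset(pd.DataFrame({"q": [3.0]}))
        with pytest.warns(UserWarning, match="unseen"):
            out, _ = b.encode_and_impute(test, b.PrepConfig(), maps=maps)
        assert out.frame["q"].tolist() == [0]


class TestStandardize:
    def test_unit_moments_and_inverse(self):
        rng = np.random.default_rng(1)
        train = make_dataset(pd.DataFrame({"x": rng.integers(1, 5, 200).astype(float)}))
        z, _, stats = b.standardize(train)
        assert abs(z["x"].mean()) < 1e-9
        assert abs(z["x"].std(ddof=0) - 1) < 1e-9
        recovered = z["x"] * stats.sd["x"] + stats.mean["x"]
        np.testing.assert_allclose(recovered, train.frame["x"], atol=1e-9)

    def test_constant_test_column_finite(self):
        train = make_dataset(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        test = make_dataset(pd.DataFrame({"x": [2.0, 2.0]}))
        _, z_test, _ = b.standardize(train, test)
        assert np.isfinite(z_test["x"]).all()

    def test_zero_sd_is_error(self):
        train = make_dataset(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))
        with pytest.raises(ValueError, match="variance"):
            b.standardize(train)


class TestPipelineProperties:
    def test_no_leakage_statistics_from_train_only(self, survey_20k):
        """Fitted quartile edges and z-stats coincide with recomputation on train."""
        prepped = b.prepare(survey_20k, b.PrepConfig(seed=3))
        assert "age" in prepped.bin_edges
        tr_mean = prepped.train.frame[prepped.feature_names].astype(float).mean()
        pd.testing.assert_series_equal(tr_mean, prepped.stats.mean, check_names=False)
        # test z-scores use TRAIN stats: back-transform must recover test codes
        back = prepped.test_z * prepped.stats.sd + prepped.stats.mean
        np.testing.assert_allclose(
            back.to_numpy(), prepped.test.frame[prepped.feature_names].to_numpy(), atol=1e-9
        )

    def test_phq9_columns_removed_and_outcome_binary(self, prepped_20k):
        assert not [c for c in prepped_20k.train.frame.columns if c.startswith("phq9")]
        assert set(prepped_20k.train.outcome.unique()) <= {0, 1}

    def test_encoding_idempotent(self, prepped_20k):
        """Re-encoding already-encoded data with its own maps is the identity."""
        enc = prepped_20k.train
        again, _ = b.encode_and_impute(
            enc, b.PrepConfig(), maps={c: {v: v for v in enc.frame[c].unique()} for c in prepped_20k.feature_names}
        )
        np.testing.assert_array_equal(
            again.frame[prepped_20k.feature_names].to_numpy(),
            enc.frame[prepped_20k.feature_names].to_numpy(),
        )
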