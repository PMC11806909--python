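"""Feature-table IO, relabeling and the clr transform."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrnets import (
    FeatureTable,
    clr_transform,
    map_columns,
    read_feature_table,
    write_table,
)


def write_csv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadFeatureTable:
    def test_six_by_six_layout(self, tmp_path, toy_table):
        path = tmp_path / "toy.csv"
        toy_table.write_csv(path)
        table = read_feature_table(path)
        assert table.n_samples == 6
        assert table.n_features == 6
        assert table.sample_ids == toy_table.sample_ids
        assert table.feature_ids == toy_table.feature_ids
        np.testing.assert_array_equal(table.values, toy_table.values)

    def test_drop_metadata_column(self, tmp_path):
        path = write_csv(
            tmp_path / "t.csv",
            "sample,group,g__A,g__B\nS1,let,1,2\nS2,pla,3,4\n",
        )
        table = read_feature_table(path, drop_columns=["group"])
        assert table.feature_ids == ("g__A", "g__B")
        assert table.n_features == 2

    def test_na_cell_names_location(self, tmp_path):
        path = write_csv(tmp_path / "t.csv", "sample,a,b\nS1,1,2\nS2,NA,4\n")
        with pytest.raises(ValueError, match="S2.*'a'|'a'.*S2"):
            read_feature_table(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_feature_table(tmp_path / "nope.csv")

    def test_duplicate_feature_names(self, tmp_path):
        path = write_csv(tmp_path / "t.csv", "sample,a,a\nS1,1,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_feature_table(path)

    def test_unknown_drop_column(self, tmp_path):
        path = write_csv(tmp_path / "t.csv", "sample,a\nS1,1\nS2,2\n")
        with pytest.raises(ValueError, match="drop_columns"):
            read_feature_table(path, drop_columns=["nope"])

    def test_transpose(self, tmp_path):
        path = write_csv(tmp_path / "t.csv", "feature,S1,S2\na,1,2\nb,3,4\n")
        table = read_feature_table(path, transpose=True)
        assert table.sample_ids == ("S1", "S2")
        assert table.feature_ids == ("a", "b")
        np.testing.assert_array_equal(table.values, [[1, 3], [2, 4]])


class TestMapColumns:
    def test_order_preserving_relabel(self):
        table = FeatureTable(
            ("S1", "S2"), ("g__Bacteroides", "g__Lactobacillus"), np.ones((2, 2))
        )
        relabeled, name_map = map_columns(table)
        assert relabeled.feature_ids == ("X1", "X2")
        assert name_map.original("X1") == "g__Bacteroides"
        assert name_map.original("X2") == "g__Lactobacillus"

    def test_round_trip_identity(self, toy_table):
        relabeled, name_map = map_columns(toy_table)
        recovered = tuple(name_map.original(x) for x in relabeled.feature_ids)
        assert recovered == toy_table.feature_ids
        assert name_map.standard("B3") == "X3"

    def test_singleton(self):
        table = FeatureTable(("S1", "S2"), ("only",), np.ones((2, 1)))
        relabeled, _ = map_columns(table)
        assert relabeled.feature_ids == ("X1",)

    def test_name_map_csv_round_trip(self, tmp_path, toy_table):
        _, name_map = map_columns(toy_table)
        path = tmp_path / "map.csv"
        name_map.write_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["standardized", "original"]
        assert dict(zip(frame.standardized, frame.original)) == dict(name_map.to_original)


class TestClrTransform:
    def test_constant_row_maps_to_zero(self):
        table = FeatureTable(("S1",), ("a", "b", "c", "d"), [[1.0, 1.0, 1.0, 1.0]])
        out = clr_transform(table, pseudocount=1.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_two_feature_row_closed_form(self):
        # log2 and log4 centered: +/- (log4 - log2)/2 = +/- log(2)/2
        table = FeatureTable(("S1",), ("a", "b"), [[1.0, 3.0]])
        out = clr_transform(table, pseudocount=1.0)
        expected = math.log(2.0) / 2.0
        np.testing.assert_allclose(out.values, [[-expected, expected]], atol=5e-5)
        assert round(out.values[0, 1], 4) == 0.3466

    def test_negative_input_rejected(self):
        table = FeatureTable(("S1",), ("a", "b"), [[1.0, -0.5]])
        with pytest.raises(ValueError, match="negative"):
            clr_transform(table)

    def test_bad_pseudocount(self, toy_table):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(toy_table, pseudocount=0.0)

    @given(
        st.lists(
            st.lists(st.floats(0.0, 1e6), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        ),
        st.floats(0.01, 10.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rows_sum_to_zero(self, rows, pseudocount):
        table = FeatureTable(
            tuple(f"S{i}" for i in range(len(rows))), ("a", "b", "c"), rows
        )
        out = clr_transform(table, pseudocount)
        np.testing.assert_allclose(out.values.sum(axis=1), 0.0, atol=1e-10)

    def test_scaling_invariance_of_shifted_values(self, rng):
        # clr(k * (x + c)) == clr(x + c): multiplying the shifted vector by a
        # positive constant only shifts every log, which centering removes
        shifted = rng.uniform(0.5, 20.0, size=(5, 8))
        base = FeatureTable([f"S{i}" for i in range(5)], [f"f{j}" for j in range(8)], shifted)
        scaled = FeatureTable(base.sample_ids, base.feature_ids, 7.3 * shifted)
        # pseudocount ~0 so the transform acts on the given positive values
        out_base = clr_transform(base, pseudocount=1e-12)
        out_scaled = clr_transform(scaled, pseudocount=1e-12)
        np.testing.assert_allclose(out_base.values, out_scaled.values, atol=1e-8)


class TestWriteTable:
    def test_round_trip_long_summary(self, tmp_path):
        rows = [
            {"project": p, "metric": m, "mean": 0.123456789012 * (i + 1)}
            for i, (p, m) in enumerate(
                (p, m) for p in ("A", "B") for m in [f"m{k}" for k in range(7)]
            )
        ]
        path = tmp_path / "summary.csv"
        write_table(rows, path)
        back = pd.read_csv(path)
        assert len(back) == 14
        np.testing.assert_allclose(back["mean"], [r["mean"] for r in rows], rtol=1e-12)

    def test_empty_rows_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_table([], path, columns=["node", "degree"])
        assert path.read_text().strip() == "node,degree"

    def test_mismatched_keys_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="identical keys"):
            write_table([{"a": 1}, {"b": 2}], tmp_path / "x.csv")

    def test_read_write_read_idempotent(self, tmp_path, toy_table):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        toy_table.write_csv(p1)
        t1 = read_feature_table(p1)
        t1.write_csv(p2)
        t2 = read_feature_table(p2)
        np.testing.assert_allclose(t2.values, t1.values, rtol=1e-12)
        assert t2.feature_ids == t1.feature_ids


class TestFeatureTableInvariants:
    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureTable(("S1", "S1"), ("a",), [[1.0], [2.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(("S1",), ("a", "b"), [[1.0]])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureTable(("S1",), ("a",), [[float("nan")]])
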