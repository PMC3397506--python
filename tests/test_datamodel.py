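"""Compound-table parsing, %F handling, and the log-transform contract."""

import math

import numpy as np
import pytest

from obqsar.datamodel import (
    ColumnSchema,
    ConsistencyError,
    FormatError,
    SchemaError,
    average_duplicate_ob,
    load_compound_table,
    transform_ob_to_logb,
    write_compound_table,
)
from obqsar.synthetic import SyntheticConfig, generate_dataset

from conftest import make_record


@pytest.mark.parametrize(
    "ob,expected",
    [(100.0, 2.0), (1.0, 0.0), (50.0, math.log10(50.0)), (10.0, 1.0)],
)
def test_logb_is_common_logarithm(ob, expected):
    assert transform_ob_to_logb(ob) == pytest.approx(expected, abs=1e-12)


def test_logb_rejects_nonpositive():
    with pytest.raises(ValueError):
        transform_ob_to_logb(0.0)
    with pytest.raises(ValueError):
        transform_ob_to_logb(-5.0)


class TestAverageDuplicates:
    def test_mean_on_percent_scale(self):
        recs = [make_record("A", 20.0), make_record("A", 40.0)]
        out = average_duplicate_ob(recs)
        assert len(out) == 1
        assert out[0].ob_percent == pytest.approx(30.0)
        # averaging happens before the log transform: log10(30), not mean of logs
        assert out[0].logb == pytest.approx(math.log10(30.0))
        assert out[0].logb != pytest.approx(
            (math.log10(20.0) + math.log10(40.0)) / 2.0
        )

    def test_three_replicates(self):
        recs = [make_record("A", 10.0), make_record("A", 20.0), make_record("A", 60.0)]
        assert average_duplicate_ob(recs)[0].ob_percent == pytest.approx(30.0)

    def test_no_duplicates_identity(self):
        recs = [make_record("A", 10.0), make_record("B", 20.0)]
        out = average_duplicate_ob(recs)
        assert [r.compound_id for r in out] == ["A", "B"]
        assert [r.ob_percent for r in out] == [10.0, 20.0]

    def test_order_of_first_appearance(self):
        recs = [make_record("B", 10.0), make_record("A", 20.0), make_record("B", 30.0)]
        assert [r.compound_id for r in average_duplicate_ob(recs)] == ["B", "A"]

    def test_conflicting_descriptors_raise(self):
        recs = [
            make_record("A", 10.0, desc={"d1": 0.0, "d2": 1.0}),
            make_record("A", 20.0, desc={"d1": 9.0, "d2": 1.0}),
        ]
        with pytest.raises(ConsistencyError):
            average_duplicate_ob(recs)


class TestLoadCompoundTable:
    def _write(self, tmp_path, text, name="table.csv"):
        p = tmp_path / name
        p.write_text(text)
        return str(p)

    def test_basic_parse(self, tmp_path):
        path = self._write(
            tmp_path,
            "compound_id,ob_percent,score_cyp3a4,d1,d2\n"
            "A,20,5.5,0.1,0.2\nB,50,6.5,0.3,0.4\nC,80,7.5,0.5,0.6\n",
        )
        ds = load_compound_table(path)
        assert len(ds) == 3
        assert ds.descriptor_names == ["d1", "d2"]
        assert ds.records[1].binding_scores == {"cyp3a4": 6.5}

    def test_missing_mandatory_column(self, tmp_path):
        path = self._write(
            tmp_path, "compound_id,score_cyp3a4,d1\nA,5.5,0.1\n"
        )
        with pytest.raises(SchemaError, match="ob_percent"):
            load_compound_table(path)

    def test_out_of_range_and_unparseable_rows_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            "compound_id,ob_percent,score_cyp3a4,d1\n"
            "A,20,5.5,0.1\nB,150,6.5,0.2\nC,abc,7.5,0.3\nD,-1,4.0,0.4\n",
        )
        with pytest.warns(UserWarning):
            ds = load_compound_table(path)
        assert len(ds) == 1
        assert {i for i, _ in ds.rejected_rows} == {1, 2, 3}

    def test_roundtrip_with_generator_writer(self, tmp_path):
        cfg = SyntheticConfig(n_compounds=60, n_descriptors=8, seed=3)
        ds, _ = generate_dataset(cfg)
        path = str(tmp_path / "synth.csv")
        write_compound_table(ds, path)
        back = load_compound_table(path)
        assert len(back) == len(ds)
        assert back.descriptor_names == ds.descriptor_names
        np.testing.assert_allclose(
            back.descriptor_matrix(), ds.descriptor_matrix(), atol=1e-9
        )
        np.testing.assert_allclose(back.logb_vector(), ds.logb_vector(), atol=1e-9)

    def test_full_scale_roundtrip(self, tmp_path):
        # the paper-scale shape: 805 compounds, 1536 descriptor columns
        cfg = SyntheticConfig(n_compounds=805, n_descriptors=1536, seed=1)
        ds, _ = generate_dataset(cfg)
        path = str(tmp_path / "big.csv")
        write_compound_table(ds, path)
        back = load_compound_table(path)
        assert len(back) == 805
        assert len(back.descriptor_names) == 1536

    def test_tsv_autodetected(self, tmp_path):
        path = self._write(
            tmp_path,
            "compound_id\tob_percent\tscore_cyp3a4\td1\nA\t20\t5.5\t0.1\n",
            name="table.tsv",
        )
        assert len(load_compound_table(path)) == 1

    def test_missing_descriptor_policy(self, tmp_path):
        # d1 is 50% missing -> column dropped; d2 missing once (5%, not >5%)
        # -> that row dropped instead
        rows = []
        for i in range(20):
            d1 = "" if i % 2 == 0 else "0.1"
            d2 = "" if i == 3 else "0.2"
            rows.append(f"M{i},50,5.5,{d1},{d2}")
        path = self._write(
            tmp_path,
            "compound_id,ob_percent,score_cyp3a4,d1,d2\n" + "\n".join(rows) + "\n",
        )
        with pytest.warns(UserWarning):
            ds = load_compound_table(path)
        assert ds.descriptor_names == ["d2"]
        assert len(ds) == 19
        assert any(reason == "missing descriptor value" for _, reason in ds.rejected_rows)

    def test_duplicate_columns_rejected(self, tmp_path):
        path = self._write(
            tmp_path, "compound_id,ob_percent,score_cyp3a4,d1,d1\nA,20,5.5,0.1,0.2\n"
        )
        with pytest.raises(FormatError):
            load_compound_table(path)

    def test_custom_schema_binds_free_form_names(self, tmp_path):
        path = self._write(
            tmp_path, "mol,F%,aff3a4,d1\nA,20,5.5,0.1\n"
        )
        schema = ColumnSchema(
            compound_id="mol",
            ob_percent="F%",
            binding_scores={"cyp3a4": "aff3a4"},
        )
        ds = load_compound_table(path, schema)
        assert ds.records[0].binding_scores == {"cyp3a4": 5.5}
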