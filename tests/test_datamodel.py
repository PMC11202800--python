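"""Domain types, labeling, table I/O and complex-level splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecpdh.datamodel import (
    FeatureTable,
    assemble_features,
    label_from_ddg,
    read_feature_table,
    read_residue_table,
    split_by_complex,
    write_feature_table,
    write_residue_table,
)
from ecpdh.errors import InvalidInputError, SchemaError
from ecpdh.schema import (
    FeatureSchema,
    build_default_schema,
    conventional_names,
    load_default_schema,
)
from ecpdh.synthgen import SynthSpec, generate

from conftest import make_record


class TestLabeling:
    @pytest.mark.parametrize(
        "ddg,expected",
        [(1.0, 1), (0.999, 0), (-2.5, 0), (5.3, 1), (0.0, 0)],
    )
    def test_threshold_is_inclusive(self, ddg, expected):
        assert label_from_ddg(ddg) == expected

    def test_custom_threshold(self):
        assert label_from_ddg(0.6, threshold=0.5) == 1

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            label_from_ddg(bad)


class TestSchema:
    def test_default_dimensions(self, default_schema):
        assert len(default_schema) == 218
        assert default_schema.block_count("conventional") == 43
        assert default_schema.block_count("wavelet") == 132
        assert default_schema.block_count("emd") == 43

    def test_shipped_registry_matches_builder(self, default_schema):
        assert load_default_schema() == default_schema

    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema.from_names(["a", "a"])

    def test_conventional_subblock_sizes(self):
        names = conventional_names()
        asa = [n for n in names if n.startswith(("ASA_", "u_ASA_", "d_ASA_"))]
        dssp = [n for n in names if n.startswith("dssp_")]
        dpxcx = [n for n in names if "DPX" in n or "CX" in n]
        assert len(asa) == 24 and len(dssp) == 6 and len(dpxcx) == 12
        assert names[-1] == "donor_num"


class TestRecord:
    def test_block_length_enforced(self):
        with pytest.raises(SchemaError):
            make_record(0, dssp=np.zeros(5))

    def test_nonfinite_block_rejected(self):
        bad = np.zeros(8)
        bad[3] = np.nan
        with pytest.raises(SchemaError):
            make_record(0, asa_complex=bad)

    def test_needs_ddg_or_label(self):
        with pytest.raises(SchemaError):
            make_record(0, ddg=None, label=None)

    def test_effective_label_falls_back_to_ddg(self):
        rec = make_record(0, ddg=2.0, label=None)
        assert rec.effective_label == 1


class TestAssembly:
    def test_default_width_is_218(self, record, default_schema):
        row = assemble_features(
            record, np.zeros(132), np.zeros(43), default_schema
        )
        assert row.shape == (218,)

    def test_conventional_only_width_43(self, record):
        schema = FeatureSchema.from_names(conventional_names())
        row = assemble_features(record, np.zeros(0), np.zeros(0), schema)
        assert row.shape == (43,)
        assert np.allclose(row, record.conventional_vector())

    def test_zero_record_gives_zero_row(self, default_schema):
        rec = make_record(
            0,
            asa_complex=np.zeros(8), asa_unbound=np.zeros(8),
            asa_delta=np.zeros(8), dssp=np.zeros(6), dpx_cx=np.zeros(12),
            hbond_count=0,
        )
        row = assemble_features(rec, np.zeros(132), np.zeros(43), default_schema)
        assert not row.any()

    def test_block_length_mismatch_is_schema_error(self, record, default_schema):
        with pytest.raises(SchemaError):
            assemble_features(record, np.zeros(131), np.zeros(43), default_schema)

    @given(n_wav=st.integers(0, 20), n_emd=st.integers(0, 20))
    @settings(max_examples=20, deadline=None)
    def test_width_equals_schema_length(self, n_wav, n_emd):
        from ecpdh.schema import SchemaEntry

        entries = [SchemaEntry(n, "conventional") for n in conventional_names()]
        entries += [SchemaEntry(f"w{i}", "wavelet") for i in range(n_wav)]
        entries += [SchemaEntry(f"e{i}", "emd") for i in range(n_emd)]
        schema = FeatureSchema(tuple(entries))
        row = assemble_features(
            make_record(1), np.zeros(n_wav), np.zeros(n_emd), schema
        )
        assert row.shape == (len(schema),)


class TestTableIO:
    def _table(self, seed=0, n=7):
        rng = np.random.default_rng(seed)
        names = [f"f{j}" for j in range(5)]
        return FeatureTable(
            FeatureSchema.from_names(names),
            rng.normal(size=(n, 5)),
            rng.integers(0, 2, n),
            np.array([f"c{j % 3}" for j in range(n)], dtype=object),
        )

    def test_feature_table_roundtrip_full_precision(self, tmp_path):
        table = self._table()
        path = tmp_path / "t.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        np.testing.assert_array_equal(back.rows, table.rows)
        assert back.schema.names == table.schema.names
        np.testing.assert_array_equal(back.labels, table.labels)

    def test_tsv_dialect_roundtrip(self, tmp_path):
        table = self._table(1)
        path = tmp_path / "t.tsv"
        write_feature_table(table, path, dialect="tsv")
        back = read_feature_table(path, dialect="tsv")
        np.testing.assert_array_equal(back.rows, table.rows)

    def test_residue_table_roundtrip(self, tmp_path):
        records = generate(SynthSpec(n_complexes=3, seed=4))
        path = tmp_path / "r.csv"
        write_residue_table(records, path)
        back = read_residue_table(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            np.testing.assert_array_equal(a.asa_delta, b.asa_delta)
            np.testing.assert_array_equal(a.dssp, b.dssp)
            assert a.complex_id == b.complex_id and a.ddg == pytest.approx(b.ddg)

    def test_missing_block_is_schema_error(self, tmp_path):
        records = generate(SynthSpec(n_complexes=2, seed=4))
        path = tmp_path / "r.csv"
        write_residue_table(records, path)
        import pandas as pd

        df = pd.read_csv(path)
        df.drop(columns=[c for c in df.columns if c.startswith("dssp_")]).to_csv(
            tmp_path / "bad.csv", index=False
        )
        with pytest.raises(SchemaError):
            read_residue_table(tmp_path / "bad.csv")

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        table = self._table()
        path = tmp_path / "t.csv"
        write_feature_table(table, path)
        text = path.read_text().splitlines()
        cells = text[2].split(",")
        cells[3] = "oops"
        text[2] = ",".join(cells)
        path.write_text("\n".join(text))
        from ecpdh.errors import ParseError

        with pytest.raises(ParseError, match="f1"):
            read_feature_table(path)


class TestSplit:
    def test_counts_and_grouping(self):
        records = generate(SynthSpec(n_complexes=4, seed=0))
        split = split_by_complex(records, n_test_complexes=1, seed=7)
        groups = np.array([r.complex_id for r in records], dtype=object)
        test_ids = set(groups[split.test_indices])
        train_ids = set(groups[split.train_indices])
        assert len(test_ids) == 1
        assert not test_ids & train_ids
        assert len(split.train_indices) + len(split.test_indices) == len(records)

    def test_deterministic_per_seed(self):
        records = generate(SynthSpec(n_complexes=10, seed=0))
        a = split_by_complex(records, 3, seed=11)
        b = split_by_complex(records, 3, seed=11)
        np.testing.assert_array_equal(a.test_indices, b.test_indices)

    def test_25_of_117_complexes(self):
        records = generate(SynthSpec(n_complexes=117, seed=1))
        split = split_by_complex(records, 25, seed=0)
        groups = np.array([r.complex_id for r in records], dtype=object)
        assert len(set(groups[split.test_indices])) == 25
        assert len(set(groups[split.train_indices])) == 92

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_grouping_invariant_for_all_seeds(self, seed):
        records = generate(SynthSpec(n_complexes=8, seed=2))
        split = split_by_complex(records, 3, seed=seed)
        groups = np.array([r.complex_id for r in records], dtype=object)
        assert not set(groups[split.test_indices]) & set(groups[split.train_indices])

    def test_too_many_test_complexes_rejected(self):
        records = generate(SynthSpec(n_complexes=3, seed=0))
        with pytest.raises(InvalidInputError):
            split_by_complex(records, 3, seed=0)
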