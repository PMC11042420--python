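import numpy as np
import pandas as pd
import pytest

from organfield import organ_io as io
from organfield.errors import ConflictError, SchemaError, ValidationError


def write_long(path, rows):
    cols = ["mutation_id", "gene", "chrom", "pos", "ref", "alt",
            "variant_type", "coding_effect", "context", "field_id", "vaf"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def make_rows(vaf="0.1"):
    rows = []
    for m in range(3):
        for f in ("F1", "F2"):
            rows.append(
                [f"m{m}", f"G{m}", "1", 100 + m, "C", "T", "SNV",
                 "non_silent", "ACA", f, vaf]
            )
    return rows


class TestMutationTable:
    def test_long_shape(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_long(p, make_rows())
        records, vafs = io.read_mutation_table(p, dialect="long")
        assert vafs.shape == (3, 2)
        assert len(records) == 3
        assert np.allclose(vafs.values, 0.1)
        assert vafs.mask.all()

    def test_vaf_out_of_range_names_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = make_rows()
        rows[2][-1] = "1.5"
        write_long(p, rows)
        with pytest.raises(ValidationError, match="row 4"):
            io.read_mutation_table(p, dialect="long")

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        df = pd.DataFrame({"mutation_id": ["m1"], "vaf": ["0.1"]})
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(SchemaError):
            io.read_mutation_table(p, dialect="long")

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = make_rows()
        df = pd.DataFrame(
            rows,
            columns=["mutation_id", "gene", "chrom", "pos", "ref", "alt",
                     "variant_type", "coding_effect", "context", "field_id", "vaf"],
        )
        df["bogus"] = "x"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(SchemaError, match="bogus"):
            io.read_mutation_table(p, dialect="long")

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = make_rows()
        rows.append(rows[0])
        write_long(p, rows)
        with pytest.raises(ConflictError, match="duplicate"):
            io.read_mutation_table(p, dialect="long")

    def test_conflicting_annotation_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        rows = make_rows()
        rows[1] = list(rows[1])
        rows[1][1] = "OTHERGENE"  # same mutation_id, different gene
        write_long(p, rows)
        with pytest.raises(ConflictError):
            io.read_mutation_table(p, dialect="long")

    def test_wide_long_equivalence(self, tmp_path):
        pl = tmp_path / "long.tsv"
        write_long(pl, make_rows())
        records_l, vafs_l = io.read_mutation_table(pl, dialect="long")
        pw = tmp_path / "wide.tsv"
        io.write_mutation_table(records_l, vafs_l, pw, dialect="wide")
        records_w, vafs_w = io.read_mutation_table(pw, dialect="wide")
        assert records_l == records_w
        assert np.array_equal(vafs_l.values, vafs_w.values)
        assert np.array_equal(vafs_l.mask, vafs_w.mask)
        assert vafs_l.field_ids == vafs_w.field_ids

    def test_long_roundtrip_identity(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_long(p1, make_rows())
        records, vafs = io.read_mutation_table(p1, dialect="long")
        io.write_mutation_table(records, vafs, p2, dialect="long")
        records2, vafs2 = io.read_mutation_table(p2, dialect="long")
        assert records == records2
        assert np.array_equal(vafs.values, vafs2.values)


class TestMutationRecord:
    def test_snv_ref_alt_must_differ(self):
        with pytest.raises(ValidationError):
            io.MutationRecord("m", "G", "1", 5, "C", "C")

    def test_context_center_must_match_ref(self):
        with pytest.raises(ValidationError):
            io.MutationRecord("m", "G", "1", 5, "C", "T", context="ATA")

    def test_pos_must_be_positive(self):
        with pytest.raises(ValidationError):
            io.MutationRecord("m", "G", "1", 0, "C", "T")


class TestFieldAnnotations:
    def write(self, path, rows):
        pd.DataFrame(rows, columns=["field_id", "row", "col", "histology"]).to_csv(
            path, sep="\t", index=False
        )

    def test_38_fields(self, tmp_path):
        p = tmp_path / "f.tsv"
        codes = (["NU"] * 20 + ["LGIN"] * 9 + ["HGIN"] * 5 + ["UC"] * 4)
        self.write(p, [[f"F{i:02d}", i // 8, i % 8, codes[i]] for i in range(38)])
        organ_map = io.read_field_annotations(p)
        assert len(organ_map) == 38

    def test_unknown_histology_named(self, tmp_path):
        p = tmp_path / "f.tsv"
        self.write(p, [["F1", 0, 0, "XX"]])
        with pytest.raises(ValidationError, match="XX"):
            io.read_field_annotations(p)

    def test_lgin_groups_with_nu(self, tmp_path):
        p = tmp_path / "f.tsv"
        self.write(p, [["F1", 0, 0, "LGIN"], ["F2", 0, 1, "NU"], ["F3", 0, 2, "UC"]])
        organ_map = io.read_field_annotations(p)
        assert organ_map.groups == ["NU_LGIN", "NU_LGIN", "UC"]

    def test_duplicate_field_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        self.write(p, [["F1", 0, 0, "NU"], ["F1", 0, 1, "NU"]])
        with pytest.raises(ValidationError):
            io.read_field_annotations(p)

    def test_roundtrip(self, tmp_path, small_organ):
        _, _, organ_map, _ = small_organ
        p = tmp_path / "f.tsv"
        io.write_field_annotations(organ_map, p)
        again = io.read_field_annotations(p)
        assert again.fields == organ_map.fields


class TestSignatureMatrixIO:
    def test_cosmic_format_30_signatures(self, tmp_path, sig_matrix):
        p = tmp_path / "w.csv"
        io.write_signature_matrix(sig_matrix, p)
        sig = io.read_signature_matrix(p)
        assert sig.K == 30
        assert np.allclose(sig.W, sig_matrix.W)

    def test_bad_column_sum(self, tmp_path, sig_matrix):
        p = tmp_path / "w.csv"
        df = pd.DataFrame(
            sig_matrix.W.copy(), index=list(io.CANONICAL_MOTIFS), columns=sig_matrix.labels
        )
        df.iloc[:, 0] *= 0.8
        df.to_csv(p)
        with pytest.raises(ValidationError, match="sums to"):
            io.read_signature_matrix(p)

    def test_row_order_invariance(self, tmp_path, sig_matrix):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df = pd.DataFrame(
            sig_matrix.W, index=list(io.CANONICAL_MOTIFS), columns=sig_matrix.labels
        )
        df.to_csv(p1)
        df.sample(frac=1.0, random_state=4).to_csv(p2)
        a = io.read_signature_matrix(p1)
        b = io.read_signature_matrix(p2)
        assert np.array_equal(a.W, b.W)

    def test_negative_entry_rejected(self, tmp_path, sig_matrix):
        p = tmp_path / "w.csv"
        W = sig_matrix.W.copy()
        W[0, 0] -= 2e-7  # keep the column sum within tolerance
        W[np.argmax(W[:, 0]), 0] += 2e-7
        W[0, 0] = -1e-7
        df = pd.DataFrame(W, index=list(io.CANONICAL_MOTIFS), columns=sig_matrix.labels)
        df.to_csv(p)
        with pytest.raises(ValidationError, match="negative"):
            io.read_signature_matrix(p)

    def test_wrong_row_count(self, tmp_path, sig_matrix):
        p = tmp_path / "w.csv"
        df = pd.DataFrame(
            sig_matrix.W, index=list(io.CANONICAL_MOTIFS), columns=sig_matrix.labels
        )
        df.iloc[:-1].to_csv(p)
        with pytest.raises(SchemaError, match="96"):
            io.read_signature_matrix(p)


def test_canonical_motif_order():
    motifs = io.canonical_motifs()
    assert len(motifs) == 96
    assert motifs[0] == "A[C>A]A"
    assert motifs[1] == "A[C>A]C"
    assert motifs[16] == "A[C>G]A"
    assert motifs[-1] == "T[T>G]T"


def test_extract_context():
    assert io.extract_context({"1": "aacgt"}, "1", 3) == "ACG"
    with pytest.raises(ValidationError):
        io.extract_context({"1": "aacgt"}, "1", 1)
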