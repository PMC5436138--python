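"""Reading, orientation and round-tripping of quantification tables."""

import math

import numpy as np
import pandas as pd
import pytest

from importomics import (
    ColumnMap,
    ProteinQuantRecord,
    ProteinSequenceRecord,
    Replicate,
    ReplicateDesign,
    read_fasta,
    read_quant_table,
    read_reference_set,
    write_results_table,
)
from importomics.quant_io import (
    EVIDENCE_ABSENT,
    QuantTableFormatError,
    quant_records_to_table,
)

from conftest import write_quant_tsv


class TestReadQuantTable:
    def test_empty_table_gives_empty_collection(self, tmp_path, design2):
        path = write_quant_tsv(tmp_path / "t.tsv", design2, [])
        assert read_quant_table(path, design2) == []

    def test_orientation_respects_label_switch(self, tmp_path, design2):
        # raw H/L 0.5 with induced heavy and 2.0 with induced light both
        # mean a two-fold depletion: oriented log2 = -1 in both replicates
        path = write_quant_tsv(
            tmp_path / "t.tsv",
            design2,
            [("P1", 3, 2, [0.5, 2.0], ["msms", "msms"])],
        )
        (record,) = read_quant_table(path, design2)
        assert record.log2_ratios == pytest.approx([-1.0, -1.0])

    def test_missing_cells_become_missing_with_absent_evidence(self, tmp_path, design2):
        path = write_quant_tsv(
            tmp_path / "t.tsv",
            design2,
            [("P1", 3, 2, [1.0, None], ["msms", "absent"])],
        )
        (record,) = read_quant_table(path, design2)
        assert math.isnan(record.log2_ratios[1])
        assert record.evidence[1] == EVIDENCE_ABSENT
        assert record.n_quantified == 1

    def test_missing_column_named_in_error(self, tmp_path, design2):
        (tmp_path / "bad.tsv").write_text("protein_id\tn_peptides\n")
        with pytest.raises(QuantTableFormatError, match="n_unique_peptides"):
            read_quant_table(tmp_path / "bad.tsv", design2)

    def test_non_positive_ratio_rejected_with_row_reference(self, tmp_path, design2):
        path = write_quant_tsv(
            tmp_path / "t.tsv",
            design2,
            [("P1", 3, 2, [-0.5, 1.0], ["msms", "msms"])],
        )
        with pytest.raises(ValueError, match="row 2"):
            read_quant_table(path, design2)

    def test_record_count_independent_of_missingness(self, tmp_path, design2):
        rows = [
            ("P1", 2, 1, [None, None], ["absent", "absent"]),
            ("P2", 2, 1, [1.5, None], ["msms", "absent"]),
            ("P3", 2, 1, [1.5, 0.7], ["msms", "msms"]),
        ]
        path = write_quant_tsv(tmp_path / "t.tsv", design2, rows)
        records = read_quant_table(path, design2)
        assert [r.protein_id for r in records] == ["P1", "P2", "P3"]

    def test_orientation_involution(self, tmp_path):
        """All-heavy and all-light designs give element-wise negated ratios."""
        all_heavy = ReplicateDesign(
            replicates=(Replicate("rep1", "heavy"), Replicate("rep2", "heavy"))
        )
        all_light = ReplicateDesign(
            replicates=(Replicate("rep1", "light"), Replicate("rep2", "light"))
        )
        path = write_quant_tsv(
            tmp_path / "t.tsv",
            all_heavy,
            [("P1", 3, 2, [0.7, 1.9], ["msms", "msms"]),
             ("P2", 3, 2, [2.2, None], ["msms", "absent"])],
        )
        heavy = read_quant_table(path, all_heavy)
        light = read_quant_table(path, all_light)
        for h, l in zip(heavy, light):
            np.testing.assert_allclose(h.log2_ratios, -l.log2_ratios)


class TestReferenceSets:
    def test_ids_parsed_and_counted(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# comment\nA\nB\nC\n")
        ref = read_reference_set(p, "toy")
        assert ref.ids == {"A", "B", "C"}

    def test_duplicates_collapse_with_warning(self, tmp_path, caplog):
        p = tmp_path / "ref.txt"
        p.write_text("A\nA\nB\n")
        with caplog.at_level("WARNING"):
            ref = read_reference_set(p, "toy")
        assert len(ref) == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# only a comment\n")
        with pytest.raises(ValueError):
            read_reference_set(p, "toy")


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">P1 some description\nCAAAC\n")
        (rec,) = read_fasta(p)
        assert (rec.protein_id, rec.sequence) == ("P1", "CAAAC")

    def test_wrapped_and_lowercase_sequences(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">P1\ncaa\nac\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "CAAAC"

    def test_duplicate_accession_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">P1\nAAA\n>P1\nCCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_illegal_residue_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            ProteinSequenceRecord("P1", "AB")


class TestWriteResultsTable:
    def test_empty_collection_writes_header_only(self, tmp_path):
        frame = pd.DataFrame(columns=["protein_id", "mean_log2"])
        out = tmp_path / "out.tsv"
        write_results_table(frame, out)
        assert out.read_text().strip() == "protein_id\tmean_log2"

    def test_quant_round_trip_preserves_ratios(self, tmp_path, design4):
        ratios = np.array([-1.234567, 0.5, np.nan, 2.0])
        rec = ProteinQuantRecord(
            protein_id="P1",
            description="d",
            n_peptides=5,
            n_unique_peptides=3,
            log2_ratios=ratios,
            evidence=("msms", "msms", "absent", "match_between_runs"),
        )
        table = quant_records_to_table([rec], design4)
        path = tmp_path / "t.tsv"
        table.to_csv(path, sep="\t", index=False)
        (back,) = read_quant_table(path, design4)
        np.testing.assert_allclose(
            back.log2_ratios[~np.isnan(ratios)], ratios[~np.isnan(ratios)], atol=1e-6
        )
        assert math.isnan(back.log2_ratios[2])
        assert back.evidence == rec.evidence

    def test_dataclass_collection_has_stable_schema(self, tmp_path):
        from importomics import ImportomeCall

        calls = [ImportomeCall("P1", -1.0, 0.01, "imported")]
        out = tmp_path / "calls.tsv"
        write_results_table(calls, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == [
            "protein_id", "mean_log2", "p_value", "call", "direction",
            "is_new_candidate",
        ]


class TestRecordInvariants:
    def test_unique_peptides_bounded_by_peptides(self):
        with pytest.raises(ValueError):
            ProteinQuantRecord("P1", "", 1, 2, np.array([0.0]), ("msms",))

    def test_absent_evidence_must_lack_ratio(self):
        with pytest.raises(ValueError):
            ProteinQuantRecord("P1", "", 2, 1, np.array([0.5]), ("absent",))

    def test_design_requires_unique_replicate_ids(self):
        with pytest.raises(ValueError):
            ReplicateDesign(
                replicates=(Replicate("r", "heavy"), Replicate("r", "light"))
            )
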