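"""Format readers/writers: round trips, coordinate conventions, dialects."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tecurate.seqio import (
    CopyAlignment,
    DomainHitRow,
    GenomicInterval,
    SequenceRecord,
    count_substitutions,
    parse_domain_table,
    parse_gff3_transcripts,
    parse_rm_align,
    read_bed,
    read_fasta,
    write_bed,
    write_fasta,
    write_rm_align,
)


class TestFasta:
    def test_round_trip_preserves_content_and_order(self, tmp_path):
        records = [
            SequenceRecord("seq1", "ACGTACGT", "first"),
            SequenceRecord("seq2", "TTTTCCCC"),
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.seq, r.description) for r in back] == [
            (r.id, r.seq, r.description) for r in records
        ]

    def test_lowercase_and_u_normalized(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">a\nacgu\n")
        assert read_fasta(path)[0].seq == "ACGT"

    def test_duplicate_id_is_hard_error_naming_id(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">dup\nACGT\n>dup\nTTTT\n")
        with pytest.raises(ValueError, match="dup"):
            read_fasta(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        path = tmp_path / "x.fasta"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fasta(path) == []
        assert "no records" in caplog.text


class TestCoordinates:
    @given(st.integers(0, 10**6), st.integers(1, 10**4))
    def test_one_based_conversion_round_trips(self, start, length):
        iv = GenomicInterval("chr1", start, start + length)
        s1, e1 = iv.to_one_based()
        assert GenomicInterval.from_one_based("chr1", s1, e1) == iv

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)

    def test_bed_round_trip(self, tmp_path):
        ivs = [
            GenomicInterval("chr1", 0, 100, "+", "a"),
            GenomicInterval("chr2", 50, 80, "-", "b"),
        ]
        path = tmp_path / "x.bed"
        write_bed(ivs, path)
        assert read_bed(path) == ivs


class TestRmAlign:
    @staticmethod
    def _write(tmp_path, blocks):
        path = tmp_path / "x.align"
        write_rm_align(path, blocks, genome_sizes={"chr1": 100_000})
        return path

    def test_identical_rows_give_zero_substitutions(self, tmp_path):
        row = "ACGT" * 25
        path = self._write(
            tmp_path, [(GenomicInterval("chr1", 0, 100), "fam1", row, row)]
        )
        (rec,) = parse_rm_align(path)
        assert (rec.aligned_sites, rec.transitions, rec.transversions) == (100, 0, 0)

    def test_single_ag_mismatch_counts_one_transition(self, tmp_path):
        cons = "ACGT" * 25
        query = "G" + cons[1:]  # A->G at position 0
        path = self._write(
            tmp_path, [(GenomicInterval("chr1", 0, 100), "fam1", query, cons)]
        )
        (rec,) = parse_rm_align(path)
        assert rec.transitions == 1 and rec.transversions == 0

    def test_truncated_block_skipped_with_warning(self, tmp_path, caplog):
        row = "ACGTACGTAC"
        path = self._write(
            tmp_path,
            [
                (GenomicInterval("chr1", 0, 10), "fam1", row, row),
                (GenomicInterval("chr1", 20, 30), "fam2", row, row),
                (GenomicInterval("chr1", 40, 50), "fam3", row, row),
            ],
        )
        # truncate the last block: keep its header, drop its aligned rows
        lines = path.read_text().splitlines()
        last_header = max(
            i for i, l in enumerate(lines) if l.startswith("10 ")
        )
        path.write_text("\n".join(lines[: last_header + 1]) + "\n")
        with caplog.at_level("WARNING"):
            records = parse_rm_align(path)
        assert len(records) == 2
        assert "skipped 1" in caplog.text

    def test_gap_and_n_columns_excluded(self):
        sites, ts, tv, _ = count_substitutions("AC-GN", "ACAGT")
        assert (sites, ts, tv) == (3, 0, 0)

    @given(st.integers(0, 2**31 - 1))
    def test_substitution_counts_partition_ungapped_columns(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        alphabet = np.array(list("ACGTN-"))
        q = "".join(rng.choice(alphabet, n, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06]))
        c = "".join(rng.choice(alphabet, n, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06]))
        sites, ts, tv, other = count_substitutions(q, c)
        ungapped = sum(
            1 for a, b in zip(q, c) if a in "ACGT" and b in "ACGT"
        )
        matches = sum(
            1 for a, b in zip(q, c) if a in "ACGT" and b in "ACGT" and a == b
        )
        assert sites == ungapped
        assert matches + ts + tv + other == ungapped


class TestGff3:
    GFF = (
        "##gff-version 3\n"
        "chr1\t.\tmRNA\t1001\t2000\t.\t+\t.\tID=t1\n"
        "chr1\t.\texon\t1001\t1500\t.\t+\t.\tID=e1\n"
        "chr1\t.\tmRNA\t3000\t2500\t.\t+\t.\tID=bad\n"
        "chr2\t.\ttranscript\t10\t50\t.\t-\t.\tID=t2\n"
    )

    def test_coordinates_strand_and_type_filter(self, tmp_path, caplog):
        path = tmp_path / "x.gff3"
        path.write_text(self.GFF)
        with caplog.at_level("WARNING"):
            ivs = parse_gff3_transcripts(path)
        assert [iv.label for iv in ivs] == ["t1", "t2"]
        assert (ivs[0].start, ivs[0].end, ivs[0].strand) == (1000, 2000, "+")
        assert ivs[1].strand == "-"
        assert "end < start" in caplog.text


class TestDomainTable:
    def test_minimal_dialect_with_comments(self, tmp_path):
        path = tmp_path / "x.tbl"
        path.write_text(
            "# comment line\n"
            "q1\tRT-Gypsy\t120.5\t1e-30\t3\t200\n"
            "q2\ttransposase-hAT\t88\t2e-20\t1\t150\n"
            "q3\tRT-LINE\t50\t1e-5\t-3\t100\n"  # negative coord -> rejected
            "q4\tRT-LINE\t45\t1e-4\t10\t90\n"
        )
        rows = parse_domain_table(path)
        assert [r.query_id for r in rows] == ["q1", "q2", "q4"]
        assert rows[0].e_value == pytest.approx(1e-30)

    def test_domtblout_dialect(self, tmp_path):
        fields = (
            "cons1 - 500 RT-Gypsy - 210 1.2e-50 170.0 0.1 1 1 "
            "2.2e-49 1.1e-45 165.3 0.1 5 200 10 205 8 208 0.98 desc here"
        )
        path = tmp_path / "x.domtbl"
        path.write_text("# full table\n" + fields + "\n")
        (row,) = parse_domain_table(path)
        assert row.query_id == "cons1"
        assert row.profile_name == "RT-Gypsy"
        assert row.bit_score == pytest.approx(165.3)
        assert (row.ali_start, row.ali_end) == (10, 205)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DomainHitRow("q", "p", 10.0, -1.0, 1, 10)
        with pytest.raises(ValueError):
            CopyAlignment(GenomicInterval("c", 0, 10), "f", 5, 4, 3)
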