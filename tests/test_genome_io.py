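import gzip

import numpy as np
import pytest

from isoscreen import genome_io
from isoscreen.genome_io import (
    CoverageTrack,
    FormatError,
    GeneLocus,
    SequenceRecord,
    TranscriptModel,
    read_bedgraph,
    read_fasta,
    read_gff3_cds,
    write_bedgraph,
    write_fasta,
)


class TestSequenceRecord:
    def test_uppercased(self):
        rec = SequenceRecord("a", "acgt")
        assert rec.residues == "ACGT"

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            SequenceRecord("a", "AC!T")

    def test_protein_alphabet(self):
        SequenceRecord("p", "MEEEIAALVI", alphabet="protein")
        with pytest.raises(ValueError):
            SequenceRecord("p", "ME1", alphabet="protein")


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "a"
        assert recs[0].residues == "ACGT"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_wrapped_record_concatenates(self, tmp_path):
        # oracle: naive concatenation of the three 60-nt lines
        lines = ["A" * 60, "C" * 60, "G" * 60]
        p = tmp_path / "w.fa"
        p.write_text(">x desc here\n" + "\n".join(lines) + "\n")
        recs = read_fasta(p)
        assert recs[0].residues == "".join(lines)
        assert len(recs[0].residues) == 180
        assert recs[0].description == "desc here"

    def test_illegal_character_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\nACGT\nAC%T\n")
        with pytest.raises(FormatError, match=":3"):
            read_fasta(p)

    def test_data_before_header(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n")
        with pytest.raises(FormatError, match=":1"):
            read_fasta(p)

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "multi.fa"
        p.write_text(">b\nAA\n>a\nCC\n>c\nGG\n")
        assert [r.id for r in read_fasta(p)] == ["b", "a", "c"]

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "a.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">a\nACGT\n")
        assert read_fasta(p)[0].residues == "ACGT"

    def test_roundtrip_exact(self, tmp_path):
        recs = [
            SequenceRecord("one", "ACGT" * 40, description="first"),
            SequenceRecord("two", "GGCC"),
        ]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.description, r.residues) for r in back] == [
            (r.id, r.description, r.residues) for r in recs
        ]


class TestTranscriptModel:
    def test_length_and_frame(self):
        tx = TranscriptModel("t1", "g1", "chr1", "+", [(0, 300), (400, 550)])
        assert tx.cds_length == 450
        assert tx.in_frame

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            TranscriptModel("t1", "g1", "chr1", "+", [(0, 10), (5, 20)])

    def test_minus_strand_order_enforced(self):
        # transcript orientation on '-' is descending genomic order
        TranscriptModel("t1", "g1", "chr1", "-", [(300, 345), (200, 260)])
        with pytest.raises(ValueError, match="orientation"):
            TranscriptModel("t1", "g1", "chr1", "-", [(200, 260), (300, 345)])


class TestReadGff3:
    GFF = "##gff-version 3\n{rows}"

    def _write(self, tmp_path, rows):
        p = tmp_path / "ann.gff3"
        p.write_text(self.GFF.format(rows=rows))
        return p

    def test_coordinate_convention(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\tx\tCDS\t100\t149\t.\t+\t0\tParent=t1;gene_id=g1\n",
        )
        loci = read_gff3_cds(p)
        assert loci[0].transcripts[0].cds_segments == [(99, 149)]

    def test_halfopen_width_matches_inclusive_width(self, tmp_path):
        # invariant: (end - start) == inclusive_end - inclusive_start + 1
        p = self._write(
            tmp_path, "chr1\tx\tCDS\t7\t21\t.\t+\t0\tParent=t1;gene_id=g1\n"
        )
        (s, e), = read_gff3_cds(p)[0].transcripts[0].cds_segments
        assert e - s == 21 - 7 + 1

    def test_minus_strand_transcript_order(self, tmp_path):
        # oracle: manual strand flip of two genomic segments
        rows = (
            "chr1\tx\tCDS\t201\t260\t.\t-\t0\tParent=t1;gene_id=g1\n"
            "chr1\tx\tCDS\t301\t345\t.\t-\t0\tParent=t1;gene_id=g1\n"
        )
        p = self._write(tmp_path, rows)
        tx = read_gff3_cds(p)[0].transcripts[0]
        assert tx.cds_segments == [(300, 345), (200, 260)]

    def test_spliced_length_and_frame_flag(self, tmp_path):
        rows = (
            "chr1\tx\tCDS\t1\t300\t.\t+\t0\tParent=t1;gene_id=g1\n"
            "chr1\tx\tCDS\t401\t550\t.\t+\t0\tParent=t1;gene_id=g1\n"
        )
        tx = read_gff3_cds(self._write(tmp_path, rows))[0].transcripts[0]
        assert tx.cds_length == 450
        assert tx.in_frame

    def test_missing_parent_errors(self, tmp_path):
        p = self._write(tmp_path, "chr1\tx\tCDS\t1\t9\t.\t+\t0\tID=orphan\n")
        with pytest.raises(FormatError, match="transcript"):
            read_gff3_cds(p)

    def test_overlapping_segments_error(self, tmp_path):
        rows = (
            "chr1\tx\tCDS\t1\t30\t.\t+\t0\tParent=t1;gene_id=g1\n"
            "chr1\tx\tCDS\t20\t60\t.\t+\t0\tParent=t1;gene_id=g1\n"
        )
        with pytest.raises(ValueError, match="overlap"):
            read_gff3_cds(self._write(tmp_path, rows))

    def test_grouping_by_gene(self, tmp_path):
        rows = (
            "chr1\tx\tCDS\t1\t30\t.\t+\t0\tParent=t1;gene_id=g1\n"
            "chr1\tx\tCDS\t1\t30\t.\t+\t0\tParent=t2;gene_id=g1\n"
            "chr2\tx\tCDS\t1\t30\t.\t+\t0\tParent=t3;gene_id=g2\n"
        )
        loci = read_gff3_cds(self._write(tmp_path, rows))
        assert [l.gene_id for l in loci] == ["g1", "g2"]
        assert len(loci[0].transcripts) == 2


class TestBedgraph:
    def test_interval_expansion(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t10\t13\t2.5\n")
        track = read_bedgraph(p)
        assert [track.density_at("chr1", i) for i in (10, 11, 12, 13)] == [
            2.5, 2.5, 2.5, 0.0,
        ]

    def test_absent_chromosome_is_zero(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t5\t1.0\n")
        track = read_bedgraph(p)
        assert track.density_at("chr2", 3) == 0.0
        assert np.all(track.region_values("chr2", 0, 10) == 0)

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t5\t1.0\nchr1\t3\t8\t1.0\n")
        with pytest.raises(FormatError, match="overlap"):
            read_bedgraph(p)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t5\t-1.0\n")
        with pytest.raises(FormatError, match="negative"):
            read_bedgraph(p)

    def test_total_mass_invariant(self, tmp_path):
        lines = [("chr1", 0, 5, 1.5), ("chr1", 10, 12, 3.0), ("chr2", 0, 7, 0.5)]
        p = tmp_path / "t.bedgraph"
        p.write_text("".join(f"{c}\t{s}\t{e}\t{v}\n" for c, s, e, v in lines))
        track = read_bedgraph(p)
        expected = sum(v * (e - s) for _, s, e, v in lines)
        assert track.total_mass() == pytest.approx(expected)

    def test_track_header_lines_skipped(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text('track type=bedGraph name="x"\n# comment\nchr1\t0\t2\t1\n')
        assert read_bedgraph(p).total_mass() == 2.0

    def test_roundtrip(self, tmp_path):
        track = CoverageTrack("t")
        track.add_intervals("chr1", [(0, 5, 1.5), (7, 9, 2.0)])
        p = tmp_path / "out.bedgraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p)
        assert back.intervals("chr1") == track.intervals("chr1")

    def test_region_values_partial_overlap(self):
        track = CoverageTrack("t")
        track.add_intervals("chr1", [(5, 10, 2.0)])
        vals = track.region_values("chr1", 3, 8)
        assert vals.tolist() == [0, 0, 2.0, 2.0, 2.0]


class TestGeneLocus:
    def test_gene_id_consistency(self):
        tx = TranscriptModel("t1", "g1", "chr1", "+", [(0, 9)])
        with pytest.raises(ValueError):
            GeneLocus("g2", [tx])
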