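import string

import pytest
from hypothesis import given, strategies as st

import pitkit as pk
from pitkit.formats_io import BLAST6_COLUMNS, write_blast_tabular


# ---------------------------------------------------------------- FASTA

class TestFasta:
    def test_multiline_concatenation(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">t1 demo\nATG\nCCC\n")
        assert pk.read_fasta(p) == [pk.FastaRecord("t1", "demo", "ATGCCC")]

    def test_crlf_and_empty_file(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\r\nAC\r\nGT\r\n")
        assert pk.read_fasta(p)[0].sequence == "ACGT"
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        assert pk.read_fasta(empty) == []

    @pytest.mark.parametrize(
        "text, fragment",
        [
            (">a\nAA\n>a\nCC\n", "duplicate"),
            ("ACGT\n", "before any header"),
            (">a\n>b\nAA\n", "empty sequence"),
        ],
    )
    def test_dialect_violations(self, tmp_path, text, fragment):
        p = tmp_path / "bad.fa"
        p.write_text(text)
        with pytest.raises(pk.FormatError, match=fragment):
            pk.read_fasta(p)

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet=string.ascii_letters + string.digits, min_size=1, max_size=12),
                st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=200),
            ),
            min_size=1,
            max_size=50,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip(self, tmp_path_factory, entries):
        """write(read(write(x))) preserves ids and sequences exactly."""
        d = tmp_path_factory.mktemp("fa")
        records = [pk.FastaRecord(i, "", s) for i, s in entries]
        pk.write_fasta(records, d / "one.fa", width=17)
        back = pk.read_fasta(d / "one.fa")
        assert [(r.id, r.sequence) for r in back] == entries
        pk.write_fasta(back, d / "two.fa", width=17)
        assert (d / "one.fa").read_text() == (d / "two.fa").read_text()


# ---------------------------------------------------------------- PSM TSV

class TestPsmTable:
    def test_parse_and_defaults(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text("spectrum_id\tpeptide\tscore\ns1\tPEPTIDEK\t12.5\ns2\tAAAR\t7\n")
        psms = pk.read_psm_table(p)
        assert [r.score for r in psms] == [12.5, 7.0]
        assert psms[0].modifications == "" and psms[0].protein_hint == ""

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text("spectrum_id\tscore\ns1\t5\n")
        with pytest.raises(pk.FormatError, match="peptide"):
            pk.read_psm_table(p)

    def test_unparseable_score_names_line(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text("spectrum_id\tpeptide\tscore\ns1\tAAK\tok?\n")
        with pytest.raises(pk.FormatError, match="line 2"):
            pk.read_psm_table(p)

    def test_write_read_round_trip(self, tmp_path):
        psms = [
            pk.PsmRecord(f"s{i}", "PEPK", float(i), modifications="ox" if i % 2 else "",
                         protein_hint=f"P{i}")
            for i in range(1000)
        ]
        p = tmp_path / "psms.tsv"
        pk.write_psm_table(psms, p)
        back = pk.read_psm_table(p)
        assert back == psms


# ---------------------------------------------------------------- BLAST

class TestBlastTabular:
    def test_single_hit(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t98.0\t50\t1\t0\t1\t50\t1\t50\t1e-40\t180\n")
        (hit,) = pk.read_blast_tabular(p)
        assert hit.evalue == 1e-40 and hit.bitscore == 180.0
        assert hit.query_id == "q1" and hit.aln_length == 50

    def test_empty_and_short_line(self, tmp_path):
        empty = tmp_path / "e.tsv"
        empty.write_text("")
        assert pk.read_blast_tabular(empty) == []
        short = tmp_path / "s.tsv"
        short.write_text("q1\ts1\t98.0\n")
        with pytest.raises(pk.FormatError, match="line 1"):
            pk.read_blast_tabular(short)

    def test_round_trip_with_extras(self, tmp_path):
        hits = [
            pk.BlastHit(f"q{i}", f"s{i}", 90.0 + i % 10, 50 + i, i % 3, 0, 1, 50,
                        1, 50, 10.0 ** -(20 + i % 30), 100.0 + i, extra=(f"x{i}",))
            for i in range(100)
        ]
        p = tmp_path / "h.tsv"
        write_blast_tabular(hits, p)
        assert pk.read_blast_tabular(p) == hits
        assert len(BLAST6_COLUMNS) == 12


# ---------------------------------------------------------------- GFF3 / alignments

class TestGff3:
    def test_serialization_example(self, tmp_path):
        feat = pk.Gff3Feature("chr1", "pitkit", "peptide", 107, 110, None, "+", 0,
                              {"ID": "pep1"})
        p = tmp_path / "f.gff3"
        pk.write_gff3([feat], p)
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert lines[1] == "chr1\tpitkit\tpeptide\t107\t110\t.\t+\t0\tID=pep1"

    def test_empty_list_writes_only_pragma(self, tmp_path):
        p = tmp_path / "f.gff3"
        pk.write_gff3([], p)
        assert p.read_text() == "##gff-version 3\n"

    def test_refuses_invalid_feature(self, tmp_path):
        feat = pk.Gff3Feature("chr1", "x", "y", 10, 5, None, "+", ".", {"ID": "bad"})
        with pytest.raises(ValueError, match="bad"):
            pk.write_gff3([feat], tmp_path / "f.gff3")

    def test_write_read_write_idempotent(self, tmp_path):
        import random

        rnd = random.Random(0)
        feats = []
        for i in range(100):
            start = rnd.randint(1, 10_000)
            feats.append(
                pk.Gff3Feature(
                    f"chr{rnd.randint(1, 3)}", "src", "exon", start,
                    start + rnd.randint(0, 500),
                    None if rnd.random() < 0.5 else round(rnd.uniform(0, 1), 3),
                    rnd.choice("+-."), rnd.choice([0, 1, 2, "."]),
                    {"ID": f"f{i}", "Note": "semi;colon=and,comma %"},
                )
            )
        pk.write_gff3(feats, tmp_path / "one.gff3")
        back = pk.read_gff3(tmp_path / "one.gff3")
        pk.write_gff3(back, tmp_path / "two.gff3")
        assert (tmp_path / "one.gff3").read_text() == (tmp_path / "two.gff3").read_text()
        assert back[0].attributes["Note"] == "semi;colon=and,comma %"


class TestTranscriptAlignments:
    def _write(self, tmp_path, strand):
        p = tmp_path / "aln.gff3"
        p.write_text(
            "##gff-version 3\n"
            f"chr1\tgmap\tmRNA\t101\t220\t.\t{strand}\t.\tID=t1\n"
            f"chr1\tgmap\texon\t101\t110\t.\t{strand}\t.\tID=t1.e1;Parent=t1\n"
            f"chr1\tgmap\texon\t201\t220\t.\t{strand}\t.\tID=t1.e2;Parent=t1\n"
        )
        return p

    def test_forward_blocks(self, tmp_path):
        (aln,) = pk.read_transcript_alignments(self._write(tmp_path, "+"))
        assert aln.blocks == [(0, 10, 100, 110), (10, 30, 200, 220)]
        assert aln.aligned_length == 30

    def test_reverse_transcript_zero_at_genome_end(self, tmp_path):
        (aln,) = pk.read_transcript_alignments(self._write(tmp_path, "-"))
        # transcript coordinate 0 sits in the rightmost genome block
        assert aln.blocks[0] == (0, 20, 200, 220)
        (seg,) = pk.project_interval(aln, 0, 1)
        assert seg == (219, 220)

    def test_gtf_attributes_accepted(self, tmp_path):
        p = tmp_path / "aln.gtf"
        p.write_text('chr1\tcuff\texon\t1\t50\t.\t+\t.\tgene_id "g1"; transcript_id "t9";\n')
        (aln,) = pk.read_transcript_alignments(p)
        assert aln.transcript_id == "t9" and aln.blocks == [(0, 50, 0, 50)]

    def test_end_before_start_is_format_error(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tgmap\texon\t50\t10\t.\t+\t.\tParent=t1\n")
        with pytest.raises(pk.FormatError):
            pk.read_transcript_alignments(p)

    def test_mixed_strand_rejected_with_diagnostic(self, tmp_path):
        p = tmp_path / "mix.gff3"
        p.write_text(
            "chr1\tgmap\texon\t1\t10\t.\t+\t.\tParent=t1\n"
            "chr1\tgmap\texon\t21\t30\t.\t-\t.\tParent=t1\n"
            "chr1\tgmap\texon\t41\t50\t.\t+\t.\tParent=t2\n"
        )
        alns, diags = pk.read_transcript_alignments(p, errors="collect")
        assert [a.transcript_id for a in alns] == ["t2"]
        assert diags == ["t1: exons on mixed strands"]

    def test_overlapping_exons_rejected(self, tmp_path):
        p = tmp_path / "ovl.gff3"
        p.write_text(
            "chr1\tgmap\texon\t1\t20\t.\t+\t.\tParent=t1\n"
            "chr1\tgmap\texon\t15\t30\t.\t+\t.\tParent=t1\n"
        )
        with pytest.raises(pk.FormatError, match="overlap"):
            pk.read_transcript_alignments(p)


# ---------------------------------------------------------------- SAM

class TestSamWriter:
    def test_record_and_header(self, tmp_path):
        p = tmp_path / "out.sam"
        pk.write_sam(
            [{"qname": "pep1", "flag": 0, "rname": "chr1", "pos": 107,
              "cigar": "4M90N5M", "seq": "ACGTACGTA"}],
            {"chr1": 1000}, p,
        )
        lines = p.read_text().splitlines()
        assert lines[0].startswith("@HD") and "SN:chr1\tLN:1000" in lines[1]
        fields = lines[2].split("\t")
        assert fields[0] == "pep1" and fields[3] == "107" and fields[5] == "4M90N5M"

    def test_reverse_strand_flag(self, tmp_path):
        p = tmp_path / "out.sam"
        pk.write_sam(
            [{"qname": "p", "flag": 16, "rname": "chr1", "pos": 1, "cigar": "9M"}],
            {"chr1": 100}, p,
        )
        assert p.read_text().splitlines()[-1].split("\t")[1] == "16"

    def test_unknown_reference_and_overflow(self, tmp_path):
        rec = {"qname": "p", "flag": 0, "rname": "chrX", "pos": 1, "cigar": "5M"}
        with pytest.raises(ValueError, match="chrX"):
            pk.write_sam([rec], {"chr1": 100}, tmp_path / "a.sam")
        rec2 = {"qname": "p", "flag": 0, "rname": "chr1", "pos": 99, "cigar": "5M"}
        with pytest.raises(ValueError, match="exceeds"):
            pk.write_sam([rec2], {"chr1": 100}, tmp_path / "b.sam")

    def test_pysam_parses_identically(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        p = tmp_path / "out.sam"
        records = [
            {"qname": f"p{i}", "flag": 16 if i % 2 else 0, "rname": "chr1",
             "pos": 10 * i + 1, "cigar": "4M10N5M", "seq": "ACGTACGTA"}
            for i in range(1, 10)
        ]
        pk.write_sam(records, {"chr1": 10_000}, p)
        with pysam.AlignmentFile(str(p), "r") as fh:
            parsed = list(fh)
        assert [(r.query_name, r.flag, r.reference_start + 1, r.cigarstring)
                for r in parsed] == [
            (r["qname"], r["flag"], r["pos"], r["cigar"]) for r in records
        ]


def test_mzid_minimal_reader(tmp_path):
    """A minimal mzIdentML 1.1 document yields spectrum id, peptide, score, decoy flag."""
    doc = """<?xml version="1.0" encoding="UTF-8"?>
<MzIdentML xmlns="http://psidev.info/psi/pi/mzIdentML/1.1" version="1.1.0"
 id="x" creationDate="2015-01-01T00:00:00">
 <SequenceCollection>
  <DBSequence id="DBSeq_P1" accession="P1" searchDatabase_ref="SDB"/>
  <DBSequence id="DBSeq_D1" accession="DECOY_P1" searchDatabase_ref="SDB"/>
  <Peptide id="Pep_1"><PeptideSequence>ELVISLIVESK</PeptideSequence></Peptide>
  <Peptide id="Pep_2"><PeptideSequence>KSEVILSIVLE</PeptideSequence></Peptide>
  <PeptideEvidence id="PE_1" peptide_ref="Pep_1" dBSequence_ref="DBSeq_P1" isDecoy="false"/>
  <PeptideEvidence id="PE_2" peptide_ref="Pep_2" dBSequence_ref="DBSeq_D1" isDecoy="true"/>
 </SequenceCollection>
 <DataCollection>
  <Inputs><SearchDatabase id="SDB" location="db.fa"/>
   <SpectraData id="SD" location="run.mzML"><SpectrumIDFormat/></SpectraData></Inputs>
  <AnalysisData>
   <SpectrumIdentificationList id="SIL">
    <SpectrumIdentificationResult id="SIR_1" spectrumID="index=0" spectraData_ref="SD">
     <SpectrumIdentificationItem id="SII_1" rank="1" chargeState="2"
       experimentalMassToCharge="500.1" calculatedMassToCharge="500.1"
       peptide_ref="Pep_1" passThreshold="true">
      <PeptideEvidenceRef peptideEvidence_ref="PE_1"/>
      <cvParam cvRef="PSI-MS" accession="MS:1002053" name="MS-GF:EValue" value="1.5e-10"/>
     </SpectrumIdentificationItem>
     <SpectrumIdentificationItem id="SII_2" rank="2" chargeState="2"
       experimentalMassToCharge="500.1" calculatedMassToCharge="500.2"
       peptide_ref="Pep_2" passThreshold="false">
      <PeptideEvidenceRef peptideEvidence_ref="PE_2"/>
      <cvParam cvRef="PSI-MS" accession="MS:1002053" name="MS-GF:EValue" value="0.5"/>
     </SpectrumIdentificationItem>
    </SpectrumIdentificationResult>
   </SpectrumIdentificationList>
  </AnalysisData>
 </DataCollection>
</MzIdentML>
"""
    p = tmp_path / "small.mzid"
    p.write_text(doc)
    psms = pk.read_mzid_psms(p)
    assert len(psms) == 2
    target = next(r for r in psms if r.peptide == "ELVISLIVESK")
    decoy = next(r for r in psms if r.peptide == "KSEVILSIVLE")
    assert target.score == pytest.approx(1.5e-10) and not target.is_decoy
    assert decoy.is_decoy and decoy.spectrum_id == "index=0"
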