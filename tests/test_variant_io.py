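"""Input parsing (table / VCF / pgSnp) and output writing."""

import gffutils
import pytest

from varannot import (InMemoryGenome, annotate_variants, export_gff,
                      parse_pgsnp, parse_variant_table, parse_vcf,
                      summarize, write_basic, write_detailed, write_report)
from varannot.fixtures import write_variant_table
from varannot.variant_io import BasicRow, DetailedRow, _normalize_vcf_allele_pair

from conftest import apply_edit

TABLE = """\
Name	Chromosome	RelStart	RelEnd	AltAlleles	RefAllele
var5	12	12550471	12550471	A/G	T
var7	12	12588586	12588587	—	CA
varX	1	100	100	R	T
var3	12	12506184	12506184	T	—
"""


class TestTableParsing:
    def test_heterozygous_and_gap_alleles(self):
        records, errors = parse_variant_table(TABLE)
        assert not errors
        assert [r.name for r in records] == ["var5", "var7", "varX", "var3"]
        var5, var7, varx, var3 = records
        assert var5.alt_alleles == ["A", "G"] and var5.ref_allele == "T"
        assert var7.alt_alleles == [""] and var7.ref_allele == "CA"
        assert varx.alt_alleles == ["A", "G"]  # IUPAC R expands
        assert var3.ref_allele == "" and var3.alt_alleles == ["T"]

    def test_header_autodetection(self):
        no_header = "v1\tchr1\t10\t10\tA\tC\n"
        records, errors = parse_variant_table(no_header)
        assert len(records) == 1 and not errors
        records, errors = parse_variant_table(TABLE, has_header=True)
        assert len(records) == 4

    def test_malformed_lines_reported_not_fatal(self):
        text = ("v1 chr1 10 10 A C\n"
                "broken line with wrong column count\n"
                "v2 chr1 30 20 A C\n"          # start > end
                "v3 chr1 40 40 A A\n"          # alt equals ref
                "v4 chr1 50 50 G T\n")
        records, errors = parse_variant_table(text, has_header=False)
        assert [r.name for r in records] == ["v1", "v4"]
        assert len(errors) == 3
        assert all(e.lineno in (2, 3, 4) for e in errors)

    def test_three_allele_input(self):
        records, _ = parse_variant_table("v chr1 5 5 A/G/T C\n",
                                         has_header=False)
        assert records[0].alt_alleles == ["A", "G", "T"]

    def test_round_trip(self, tmp_path):
        records, _ = parse_variant_table(TABLE)
        path = tmp_path / "rt.tsv"
        write_variant_table(records, path)
        again, errors = parse_variant_table(path.read_text())
        assert not errors
        assert [(r.name, r.chromosome, r.rel_start, r.rel_end, r.alt_alleles,
                 r.ref_allele) for r in again] == \
               [(r.name, r.chromosome, r.rel_start, r.rel_end, r.alt_alleles,
                 r.ref_allele) for r in records]


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=12,length=13000000>
##contig=<ID=1,length=1000000>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
12	12588585	.	TCA	T	.	.	.
1	100	.	A	G	.	.	.
1	200	rs1	A	G,T	.	.	.
1	300	ins1	T	TA	.	.	.
"""


class TestVcfParsing:
    @pytest.fixture()
    def records(self, tmp_path):
        path = tmp_path / "in.vcf"
        path.write_text(VCF_TEXT)
        records, errors = parse_vcf(str(path))
        assert not errors
        return {r.name: r for r in records}

    def test_deletion_conversion(self, records):
        deletion = records["12:12588585"]
        assert (deletion.rel_start, deletion.rel_end) == (12588586, 12588587)
        assert deletion.ref_allele == "CA" and deletion.alt_alleles == [""]

    def test_snp_and_multiallelic(self, records):
        assert records["1:100"].alt_alleles == ["G"]
        assert records["rs1"].alt_alleles == ["G", "T"]

    def test_insertion_conversion(self, records):
        ins = records["ins1"]
        assert (ins.rel_start, ins.rel_end) == (301, 301)
        assert ins.ref_allele == "" and ins.alt_alleles == ["A"]

    def test_conversion_agrees_with_apply_edit_oracle(self):
        """VCF-style and gap-style representations of the same indel
        produce identical edited sequences."""
        context = "GGTCATTTACG"  # positions 1..11
        for pos, ref, alt in [(3, "TCA", "T"), (5, "A", "ATT"),
                              (2, "GTC", "G"), (7, "T", "TTT")]:
            edited_vcf = apply_edit(context, 1, pos, ref, alt)
            s, e, ref_a, alt_a = _normalize_vcf_allele_pair(pos, ref, alt)
            edited_gap = apply_edit(context, 1, s, ref_a, alt_a)
            assert edited_vcf == edited_gap


def test_pgsnp_parsing(tmp_path):
    genome = InMemoryGenome({"chr1": "ACGTACGTAC"})
    path = tmp_path / "in.pgsnp"
    path.write_text("chr1\t4\t5\tA/G\t2\t10,12\t90,88\n"
                    "chr1\t5\t6\tT\t1\t5\t99\n")
    records, errors = parse_pgsnp(str(path), genome)
    assert not errors
    first, second = records
    assert (first.rel_start, first.rel_end) == (5, 5)
    assert first.ref_allele == "A"          # filled from the genome
    assert first.alt_alleles == ["G"]       # ref-equal allele dropped
    assert (second.rel_start, second.ref_allele) == (6, "C")
    assert second.alt_alleles == ["T"]


class TestWriters:
    def _rows(self):
        basic = [
            BasicRow("v1", "12", 100, 100, 100, 100, region="CODING_REGION",
                     variant_type="SNP", func_class="SYNONYMOUS_CODING",
                     nearest_gene="G1", distance=0, status="KNOWN",
                     ids=["rs1", "rs2"]),
            BasicRow("v2", "12", 200, 200, 200, 200, region="INTRONIC",
                     variant_type="SNP", func_class="NONE",
                     nearest_gene="G1", distance=0, status="NOVEL"),
        ]
        detailed = [
            DetailedRow("v1", "12", 100, 100, ["C"], "G", codon="GCS",
                        amino_acid="Ala", ref_amino_acid="Ala",
                        func_class="SYNONYMOUS_CODING", transcript_id="t1",
                        strand=-1, ids=["rs1", "rs2"]),
            DetailedRow("v2", "12", 200, 200, ["A"], "T",
                        func_class="INTRONIC", transcript_id="t1", strand=-1),
        ]
        return basic, detailed

    def test_text_tables(self, tmp_path):
        basic, detailed = self._rows()
        bpath, dpath = tmp_path / "b.txt", tmp_path / "d.txt"
        write_basic(basic, str(bpath))
        write_detailed(detailed, str(dpath))
        blines = bpath.read_text().splitlines()
        assert len(blines) == 3 and blines[0].startswith("Name\t")
        assert "rs1, rs2" in blines[1]          # multiple IDs comma-joined
        dlines = dpath.read_text().splitlines()
        cells = dlines[2].split("\t")
        assert "NA" in cells                    # codon columns NA off-coding

    def test_empty_input_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.txt"
        write_basic([], str(path))
        assert len(path.read_text().splitlines()) == 1

    def test_html_escaping_and_links(self, tmp_path):
        basic, _ = self._rows()
        basic[0].name = "a<b"
        path = tmp_path / "b.html"
        write_basic(basic, str(path), "html",
                    url_template="https://db.example/{id}")
        text = path.read_text()
        assert "a&lt;b" in text
        assert "https://db.example/rs1" in text

    def test_report_counts(self, tmp_path):
        basic, detailed = self._rows()
        basic.append(BasicRow("v3", "12", 5, 5, 5, 5, status="REF_MISMATCH"))
        path = tmp_path / "report.txt"
        write_report(basic, str(path), detailed)
        text = path.read_text()
        assert "variations processed: 3" in text
        assert "reference mismatches: 1" in text
        assert "SYNONYMOUS_CODING: 1" in text
        summary = summarize(basic, detailed)
        assert summary["by_status"]["REF_MISMATCH"] == 1

    def test_gff_export_parses_and_anchors_insertions(self, tmp_path):
        basic, detailed = self._rows()
        basic.append(BasicRow("ins", "12", 300, 300, 300, 300,
                              variant_type="INDEL", status="NOVEL",
                              insertion=True))
        path = tmp_path / "out.gff3"
        export_gff(basic, str(path), detailed)
        db = gffutils.create_db(str(path), ":memory:")  # format conformance
        feats = {f.id: f for f in db.all_features()}
        assert feats["v1"].attributes["func_class"] == ["SYNONYMOUS_CODING"]
        ins = feats["ins"]
        assert ins.end - ins.start + 1 == 1
        assert ins.attributes["insertion"] == ["true"]


def test_row_conservation_including_mismatches(default_bundle):
    """One basic row per input record, even for reference mismatches."""
    import dataclasses
    records = list(default_bundle.records)
    bad_ref = "G" if records[0].ref_allele != "G" else "C"
    records.append(dataclasses.replace(records[0], name="planted_mismatch",
                                       ref_allele=bad_ref))
    basic, detailed = annotate_variants(records, default_bundle.gene_index,
                                        default_bundle.genome)
    assert len(basic) == len(records)
    by_name = {r.name: r for r in basic}
    assert by_name["planted_mismatch"].status == "REF_MISMATCH"
    assert by_name["planted_mismatch"].func_class == "NONE"
    assert summarize(basic, detailed)["reference_mismatches"] == 1
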