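"""The 21-class decision tree: windows, codons, strands, indels, codes."""

import pytest

from varannot import (APPLICABILITY, ClassifierConfig, FunctionalClass as FC,
                      InMemoryGenome, Transcript, VariantRecord, VariantType,
                      classify, coding_effect, indel_coding_effect,
                      load_genetic_code, locate_in_transcript, most_severe,
                      region_class, revcomp, splice_class, start_gained_scan,
                      utr_class)
from varannot.gene_model import Exon, GeneIndex
from varannot.functional_classifier import cds_sequence

from conftest import translate_cds


# ---------------------------------------------------------------------------
# class inventory
# ---------------------------------------------------------------------------

def test_class_inventory_matrix():
    """15 classes apply to SNPs, 19 to indels, 21 in total."""
    assert len(FC) == 21
    snp_ok = [c for c in FC if VariantType.SNP in APPLICABILITY[c]]
    indel_ok = [c for c in FC if VariantType.INDEL in APPLICABILITY[c]]
    assert len(snp_ok) == 15
    assert len(indel_ok) == 19
    assert FC.SYNONYMOUS_CODING not in indel_ok
    assert FC.NON_SYNONYMOUS_CODING not in indel_ok
    assert set(FC) - set(snp_ok) == {FC.FRAMEKEEP, FC.FRAMESHIFT,
                                     FC.DELETE_EXONS, FC.MERGE_EXONS,
                                     FC.ACCEPTOR, FC.DONOR}


# ---------------------------------------------------------------------------
# region thresholds
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("distance,strand,expected", [
    (5001, 1, "INTERGENIC"), (-5001, 1, "INTERGENIC"),
    (5000, 1, "UPSTREAM"),      # gene after variant, plus strand
    (-5000, 1, "DOWNSTREAM"),   # gene before variant, plus strand
    (-500, -1, "UPSTREAM"),     # minus-strand gene ending before the variant
    (500, -1, "DOWNSTREAM"),
    (0, 1, "GENIC"),
])
def test_region_class(distance, strand, expected):
    assert region_class(distance, strand) == expected


# ---------------------------------------------------------------------------
# toy transcripts
# ---------------------------------------------------------------------------

def _toy_transcript(strand=1, coding=(120, 479)):
    # exons 100-199 / 250-349 / 400-499; introns 200-249 and 350-399
    return Transcript(
        transcript_id="toy", gene_id="toyg", chromosome="c", start=100,
        end=499, strand=strand,
        exons=[Exon(100, 199), Exon(250, 349), Exon(400, 499)],
        coding_start=coding[0] if coding else None,
        coding_end=coding[1] if coding else None)


def _splice_oracle(pos, strand):
    """Window arithmetic straight from the exon/intron coordinates."""
    exons = [(100, 199), (250, 349), (400, 499)]
    introns = [(200, 249), (350, 399)]
    expected = set()
    for istart, iend in introns:
        if istart <= pos <= iend:
            off = min(pos - istart + 1, iend - pos + 1)
            if off <= 2:
                expected.add(FC.ESSENTIAL_SPLICE_SITE)
            elif off <= 8:
                expected.add(FC.SPLICE_SITE)
    for i, (es, ee) in enumerate(exons):
        if es <= pos <= ee:
            # only junction-adjacent edges carry a splice window
            if i > 0 and pos - es + 1 <= 3:
                expected.add(FC.SPLICE_SITE)
            if i < len(exons) - 1 and ee - pos + 1 <= 3:
                expected.add(FC.SPLICE_SITE)
    return expected


@pytest.mark.parametrize("strand", [1, -1])
def test_exhaustive_splice_window_scan(strand):
    """Splice classes at every transcript position match the window
    arithmetic (intron 1-2 essential, 3-8 splice, exon edges 1-3)."""
    tx = _toy_transcript(strand=strand)
    for pos in range(100, 500):
        loc = locate_in_transcript((pos, pos), tx)
        got = splice_class(loc, tx)
        assert got == _splice_oracle(pos, strand), f"position {pos}"


def test_splice_window_spanning_variant():
    tx = _toy_transcript()
    # deletion covering intron offsets 5..12 from the 5' end: hits 5..8
    loc = locate_in_transcript((204, 211), tx)
    assert splice_class(loc, tx) == {FC.SPLICE_SITE}
    # covering offsets 1..4: both windows
    loc = locate_in_transcript((200, 203), tx)
    assert splice_class(loc, tx) == {FC.ESSENTIAL_SPLICE_SITE, FC.SPLICE_SITE}


def test_utr_orientation():
    plus = _toy_transcript(strand=1)
    minus = _toy_transcript(strand=-1)
    assert utr_class((110, 110), plus) is FC.FIVE_PRIME_UTR
    # same chromosomal position, minus-strand transcript: 3' side
    assert utr_class((110, 110), minus) is FC.THREE_PRIME_UTR
    assert utr_class((490, 490), plus) is FC.THREE_PRIME_UTR
    assert utr_class((490, 490), minus) is FC.FIVE_PRIME_UTR
    noncoding = _toy_transcript(coding=None)
    assert utr_class((110, 110), noncoding) is FC.WITHIN_NON_CODING_TRANSCRIPT
    assert utr_class((130, 130), plus) is None  # inside the coding span


# ---------------------------------------------------------------------------
# codon-level effects on a crafted single-exon gene
# ---------------------------------------------------------------------------

def _coding_genome_and_tx(cds_codons, strand=1, flank=30):
    """Single-exon transcript whose CDS is exactly ``cds_codons``."""
    cds = "".join(cds_codons)
    if strand == 1:
        seq = "T" * flank + cds + "T" * flank
    else:
        seq = "T" * flank + revcomp(cds) + "T" * flank
    genome = InMemoryGenome({"c": seq})
    tx = Transcript(transcript_id="t", gene_id="g", chromosome="c",
                    start=1, end=len(seq), strand=strand,
                    exons=[Exon(1, len(seq))],
                    coding_start=flank + 1, coding_end=flank + len(cds))
    return genome, tx


def _cds_pos(i, n_cds, strand, flank=30):
    """Genome position of CDS index i."""
    return flank + 1 + i if strand == 1 else flank + n_cds - i


CODE = load_genetic_code()


class TestCodingEffect:
    def test_stop_gained_plus_strand(self):
        genome, tx = _coding_genome_and_tx(["ATG", "TAT", "GGG", "TAA"])
        pos = _cds_pos(5, 12, 1)  # third base of codon TAT
        v = VariantRecord("v", "c", pos, pos, ["A"], "T")
        ann = coding_effect(v, tx, genome, CODE)
        assert ann.classes == {FC.STOP_GAINED}
        assert ann.codon == "TAW"

    def test_stop_lost(self):
        genome, tx = _coding_genome_and_tx(["ATG", "GGG", "TAA"])
        pos = _cds_pos(8, 9, 1)
        v = VariantRecord("v", "c", pos, pos, ["C"], "A")
        ann = coding_effect(v, tx, genome, CODE)
        assert ann.classes == {FC.STOP_LOST}
        assert ann.ref_amino_acid == "Ter"

    def test_start_lost(self):
        genome, tx = _coding_genome_and_tx(["ATG", "GGG", "TAA"])
        pos = _cds_pos(2, 9, 1)
        v = VariantRecord("v", "c", pos, pos, ["A"], "G")
        ann = coding_effect(v, tx, genome, CODE)
        assert FC.START_LOST in ann.classes
        assert FC.NON_SYNONYMOUS_CODING not in ann.classes

    def test_heterozygous_alts_joined(self):
        genome, tx = _coding_genome_and_tx(["ATG", "GCC", "TAA"])
        pos = _cds_pos(4, 9, 1)  # middle of GCC
        v = VariantRecord("v", "c", pos, pos, ["A", "T"], "C")
        ann = coding_effect(v, tx, genome, CODE)
        assert ann.classes == {FC.NON_SYNONYMOUS_CODING}
        assert ann.codon == "GHC"  # H covers {A,C,T}
        assert ann.amino_acid == "Asp/Val"
        assert ann.ref_amino_acid == "Ala"

    def test_mnp_across_codons(self):
        genome, tx = _coding_genome_and_tx(["ATG", "GCC", "AAA", "TAA"])
        pos = _cds_pos(5, 12, 1)  # last base of GCC + first of AAA
        v = VariantRecord("v", "c", pos, pos + 1, ["TC"], "CA")
        ann = coding_effect(v, tx, genome, CODE)
        assert ann.classes == {FC.NON_SYNONYMOUS_CODING}
        assert ann.codon == "GCY/MAA"

    @pytest.mark.parametrize("strand", [1, -1])
    def test_synonymous_matches_independent_translation(self, strand):
        """SYNONYMOUS iff the fully edited CDS translates identically,
        checked for every CDS position and every alternative base."""
        codons = ["ATG", "GCT", "CTG", "TAT", "CGA", "GGC", "TCA", "TAA"]
        genome, tx = _coding_genome_and_tx(codons, strand=strand)
        cds = cds_sequence(tx, genome)
        assert cds == "".join(codons)
        ref_protein = translate_cds(cds)
        n = len(cds)
        for i in range(n):
            gpos = _cds_pos(i, n, strand)
            genome_ref = genome.fetch("c", gpos, gpos)
            for alt_base in "ACGT":
                if alt_base == genome_ref:
                    continue
                v = VariantRecord("v", "c", gpos, gpos, [alt_base], genome_ref)
                ann = coding_effect(v, tx, genome, CODE)
                edited = cds[:i] + (alt_base if strand == 1 else
                                    revcomp(alt_base)) + cds[i + 1:]
                same = translate_cds(edited) == ref_protein
                assert (FC.SYNONYMOUS_CODING in ann.classes) == same, \
                    f"strand {strand}, CDS index {i}, alt {alt_base}"


def test_start_gained_scan_enumerates_windows():
    # 5' UTR context ...C A C G C...: C->T at the middle position creates
    # ATG in exactly one of the three windows
    genome, tx = _coding_genome_and_tx(["ATG", "TAA"], flank=30)
    seq = "T" * 10 + "CACGC" + "T" * 15 + "ATGTAA" + "T" * 30
    genome = InMemoryGenome({"c": seq})
    tx = Transcript(transcript_id="t", gene_id="g", chromosome="c", start=1,
                    end=len(seq), strand=1, exons=[Exon(1, len(seq))],
                    coding_start=31, coding_end=36)
    v = VariantRecord("v", "c", 13, 13, ["T"], "C")
    assert start_gained_scan(v, tx, genome)
    # destroying an existing ATG is not a gain
    v2 = VariantRecord("w", "c", 31, 31, ["C"], "A")
    assert not start_gained_scan(v2, tx, genome)
    # a substitution that leaves no ATG
    v3 = VariantRecord("x", "c", 13, 13, ["G"], "C")
    assert not start_gained_scan(v3, tx, genome)


# ---------------------------------------------------------------------------
# indel consequences
# ---------------------------------------------------------------------------

class TestIndelCodingEffect:
    tx = _toy_transcript()  # exons 100-199/250-349/400-499, CDS 120-479

    def _deletion(self, start, end):
        return VariantRecord("d", "c", start, end, [""], "X" * (end - start + 1))

    def test_frame_classes(self):
        assert indel_coding_effect(self._deletion(300, 302), self.tx) == \
            {FC.FRAMEKEEP}
        assert indel_coding_effect(self._deletion(300, 301), self.tx) == \
            {FC.FRAMESHIFT}
        insertion = VariantRecord("i", "c", 300, 300, ["TT"], "")
        assert indel_coding_effect(insertion, self.tx) == {FC.FRAMESHIFT}

    def test_structural_deletions(self):
        assert indel_coding_effect(self._deletion(240, 360), self.tx) == \
            {FC.DELETE_EXONS}          # covers exon 2 entirely
        assert indel_coding_effect(self._deletion(200, 249), self.tx) == \
            {FC.MERGE_EXONS}           # intron 1 exactly
        assert indel_coding_effect(self._deletion(245, 255), self.tx) == \
            {FC.ACCEPTOR}              # junction at exon 2 start
        assert indel_coding_effect(self._deletion(345, 355), self.tx) == \
            {FC.DONOR}                 # junction at exon 2 end

    def test_minus_strand_swaps_acceptor_donor(self):
        tx = _toy_transcript(strand=-1)
        assert indel_coding_effect(self._deletion(245, 255), tx) == {FC.DONOR}
        assert indel_coding_effect(self._deletion(345, 355), tx) == {FC.ACCEPTOR}

    def test_complex_suppresses_frame_classes(self):
        classes = indel_coding_effect(self._deletion(240, 360), self.tx)
        assert FC.FRAMESHIFT not in classes and FC.FRAMEKEEP not in classes


# ---------------------------------------------------------------------------
# genetic codes
# ---------------------------------------------------------------------------

def test_named_genetic_codes():
    standard = load_genetic_code("standard")
    assert standard.translate("ATG") == "M"
    assert standard.is_stop("TAA")
    assert "ATG" in standard.start_codons
    assert load_genetic_code("mycoplasma").translate("TGA") == "W"
    assert load_genetic_code("mitochondria").is_stop("AGA")
    assert load_genetic_code("prokaryotes").translate("ATG") == "M"
    assert len(load_genetic_code("yeasts").codons) == 64
    with pytest.raises(ValueError, match="standard"):
        load_genetic_code("klingon")


# ---------------------------------------------------------------------------
# severity / orchestration
# ---------------------------------------------------------------------------

def test_most_severe_and_positional_none():
    assert most_severe({FC.INTRONIC}) == "NONE"
    assert most_severe({FC.INTRONIC, FC.SPLICE_SITE}) == "SPLICE_SITE"
    assert most_severe({FC.SYNONYMOUS_CODING, FC.STOP_GAINED}) == "STOP_GAINED"
    assert most_severe(set()) == "NONE"


def test_strand_symmetry():
    """Annotating against a minus-strand transcript equals annotating the
    mirrored variant against the mirrored plus-strand transcript on the
    reverse-complemented genome."""
    codons = ["ATG", "GCT", "CTG", "TAT", "TAA"]
    genome, tx = _coding_genome_and_tx(codons, strand=1, flank=20)
    L = 40 + len("".join(codons))
    seq = genome.fetch("c", 1, L)
    mirror = InMemoryGenome({"c": revcomp(seq)})
    tx_m = Transcript(transcript_id="t", gene_id="g", chromosome="c",
                      start=1, end=L, strand=-1, exons=[Exon(1, L)],
                      coding_start=L - tx.coding_end + 1,
                      coding_end=L - tx.coding_start + 1)
    index = GeneIndex.from_transcripts([tx])
    index_m = GeneIndex.from_transcripts([tx_m])
    code = load_genetic_code()
    for pos in range(1, L + 1):
        ref = genome.fetch("c", pos, pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            v = VariantRecord("v", "c", pos, pos, [alt], ref)
            pos_m = L - pos + 1
            v_m = VariantRecord("v", "c", pos_m, pos_m,
                                [revcomp(alt)], revcomp(ref))
            _, anns = classify(v, index, genome, code)
            _, anns_m = classify(v_m, index_m, mirror, code)
            classes = set().union(*(a.classes for a in anns)) if anns else set()
            classes_m = set().union(*(a.classes for a in anns_m)) if anns_m \
                else set()
            assert classes == classes_m, f"position {pos} alt {alt}"
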