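"""The 21-class functional classification of variants against transcripts.

A verified variant is placed relative to the nearest gene (INTERGENIC /
UPSTREAM / DOWNSTREAM beyond or within 5 kb) or, at distance 0, classified
against every transcript of every overlapping gene: intron/exon location,
splice-site windows, UTRs, codon-level consequences under a selectable
genetic code (synonymous / nonsynonymous / stop gained / stop lost /
start lost / potential start gained), and the indel classes (framekeep /
frameshift and the complex-deletion subclasses DELETE_EXONS, MERGE_EXONS,
ACCEPTOR, DONOR).

A variant may accumulate several classes, across transcripts and within a
single transcript (a base can be both SPLICE_SITE and 3PRIME_UTR).  The
basic table carries a single FuncClass cell: the most severe non-positional
class under a configurable severity ranking, or NONE when only positional
classes apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from Bio.Data import CodonTable, IUPACData
from Bio.SeqUtils import seq3

from .gene_model import GeneIndex, Transcript, chrom_pos, revcomp, verify_ref
from .variant_io import BasicRow, DetailedRow, VariantRecord, NA
from .variant_typing import VariantType, classify_variant_type
from .indel_analysis import canonicalize

logger = logging.getLogger("varannot")


class FunctionalClass(str, Enum):
    INTERGENIC = "INTERGENIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    WITHIN_NON_CODING_TRANSCRIPT = "WITHIN_NON_CODING_TRANSCRIPT"
    INTRONIC = "INTRONIC"
    FIVE_PRIME_UTR = "5PRIME_UTR"
    THREE_PRIME_UTR = "3PRIME_UTR"
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    FRAMEKEEP = "FRAMEKEEP"
    FRAMESHIFT = "FRAMESHIFT"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    POTENTIAL_START_GAINED = "POTENTIAL_START_GAINED"
    START_LOST = "START_LOST"
    DELETE_EXONS = "DELETE_EXONS"
    MERGE_EXONS = "MERGE_EXONS"
    ACCEPTOR = "ACCEPTOR"
    DONOR = "DONOR"
    SPLICE_SITE = "SPLICE_SITE"
    ESSENTIAL_SPLICE_SITE = "ESSENTIAL_SPLICE_SITE"


FC = FunctionalClass

#: Classes that only place a variant, without a molecular consequence; a
#: variant carrying nothing beyond these gets FuncClass NONE in the basic
#: table.
POSITIONAL_CLASSES = frozenset({
    FC.INTERGENIC, FC.UPSTREAM, FC.DOWNSTREAM, FC.INTRONIC,
    FC.FIVE_PRIME_UTR, FC.THREE_PRIME_UTR, FC.WITHIN_NON_CODING_TRANSCRIPT,
})

#: Which variant types each class may be assigned to (the class inventory
#: matrix: 15 classes apply to SNPs, 19 to indels, 21 in total).
_ALL = frozenset({VariantType.SNP, VariantType.MNP, VariantType.INVERSION,
                  VariantType.INDEL})
_NO_INDEL = _ALL - {VariantType.INDEL}
_INDEL_ONLY = frozenset({VariantType.INDEL})
APPLICABILITY: dict[FunctionalClass, frozenset] = {
    FC.INTERGENIC: _ALL, FC.UPSTREAM: _ALL, FC.DOWNSTREAM: _ALL,
    FC.WITHIN_NON_CODING_TRANSCRIPT: _ALL, FC.INTRONIC: _ALL,
    FC.FIVE_PRIME_UTR: _ALL, FC.THREE_PRIME_UTR: _ALL,
    FC.SYNONYMOUS_CODING: _NO_INDEL, FC.NON_SYNONYMOUS_CODING: _NO_INDEL,
    FC.FRAMEKEEP: _INDEL_ONLY, FC.FRAMESHIFT: _INDEL_ONLY,
    FC.STOP_GAINED: _ALL, FC.STOP_LOST: _ALL,
    FC.POTENTIAL_START_GAINED: _ALL, FC.START_LOST: _ALL,
    FC.DELETE_EXONS: _INDEL_ONLY, FC.MERGE_EXONS: _INDEL_ONLY,
    FC.ACCEPTOR: frozenset({VariantType.MNP, VariantType.INVERSION,
                            VariantType.INDEL}),
    FC.DONOR: frozenset({VariantType.MNP, VariantType.INVERSION,
                         VariantType.INDEL}),
    FC.SPLICE_SITE: _ALL, FC.ESSENTIAL_SPLICE_SITE: _ALL,
}

#: Default severity ranking (most severe first) for the basic FuncClass cell.
DEFAULT_SEVERITY = [
    FC.STOP_GAINED, FC.FRAMESHIFT, FC.START_LOST, FC.STOP_LOST,
    FC.DELETE_EXONS, FC.ACCEPTOR, FC.DONOR, FC.MERGE_EXONS,
    FC.NON_SYNONYMOUS_CODING, FC.FRAMEKEEP, FC.ESSENTIAL_SPLICE_SITE,
    FC.SPLICE_SITE, FC.POTENTIAL_START_GAINED, FC.SYNONYMOUS_CODING,
]

#: Classes whose detailed rows carry codon / amino-acid columns.
CODON_CLASSES = frozenset({
    FC.SYNONYMOUS_CODING, FC.NON_SYNONYMOUS_CODING, FC.STOP_GAINED,
    FC.STOP_LOST, FC.START_LOST,
})

#: Region labels for the basic table, most genic first.
REGION_PRECEDENCE = ["CODING_REGION", "5PRIME_UTR", "3PRIME_UTR",
                     "WITHIN_NONCODING_TRANSCRIPT", "INTRONIC", "UPSTREAM",
                     "DOWNSTREAM", "INTERGENIC"]


@dataclass
class ClassifierConfig:
    """Tunables of the classification decision tree.

    distance_threshold : bp beyond which a variant is INTERGENIC (5000 —
        promoter-scale neighbourhood).
    essential_intron_window : first/last N intronic bases that are
        ESSENTIAL_SPLICE_SITE (2; set 3 for the wider reading).
    splice_intron_window : (lo, hi) intronic offsets that are SPLICE_SITE.
    splice_exon_window : first/last N exonic bases at a junction that are
        SPLICE_SITE.
    inversion_semantics : "reversal" or "revcomp" for the INVERSION type.
    severity : ranking used for the single basic-table FuncClass cell.
    """

    distance_threshold: int = 5000
    essential_intron_window: int = 2
    splice_intron_window: tuple[int, int] = (3, 8)
    splice_exon_window: int = 3
    inversion_semantics: str = "reversal"
    severity: list[FunctionalClass] = field(
        default_factory=lambda: list(DEFAULT_SEVERITY))


@dataclass
class TranscriptAnnotation:
    """Per-(variant, transcript) classification result."""

    transcript_id: str
    strand: int
    classes: set[FunctionalClass] = field(default_factory=set)
    codon: Optional[str] = None
    amino_acid: Optional[str] = None
    ref_amino_acid: Optional[str] = None
    region: str = NA


# ---------------------------------------------------------------------------
# genetic codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """A complete 64-codon translation table with start/stop sets."""

    name: str
    codons: dict  # codon -> one-letter amino acid, "*" for stop
    start_codons: frozenset
    stop_codons: frozenset

    def translate(self, codon: str) -> str:
        return self.codons[codon.upper()]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


#: Named code families -> NCBI translation table ids.
GENETIC_CODE_TABLES = {
    "standard": 1,
    "prokaryotes": 11,
    "yeasts": 12,
    "mycoplasma": 4,
    "mitochondria": 2,  # vertebrate mitochondrial
}


def load_genetic_code(name: str = "standard") -> GeneticCode:
    """Load a named genetic code (backed by the NCBI translation tables)."""
    if name not in GENETIC_CODE_TABLES:
        raise ValueError(
            f"unknown genetic code {name!r}; valid names: "
            + ", ".join(sorted(GENETIC_CODE_TABLES)))
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_TABLES[name]]
    codons = dict(table.forward_table)
    for stop in table.stop_codons:
        codons[stop] = "*"
    return GeneticCode(name=name, codons=codons,
                       start_codons=frozenset(table.start_codons),
                       stop_codons=frozenset(table.stop_codons))


_IUPAC_FOR_BASES = {frozenset(v): k for k, v in
                    IUPACData.ambiguous_dna_values.items() if len(v) <= 4}


def iupac_symbol(bases: set[str]) -> str:
    """IUPAC symbol covering a set of bases ({'C','G'} -> 'S')."""
    return _IUPAC_FOR_BASES[frozenset(b.upper() for b in bases)]


def _aa3(aa1: str) -> str:
    """One- to three-letter amino-acid code; '*' -> 'Ter'."""
    return seq3(aa1)


# ---------------------------------------------------------------------------
# region / location primitives
# ---------------------------------------------------------------------------

def region_class(distance: float, gene_strand: int,
                 threshold: int = 5000) -> str:
    """INTERGENIC / UPSTREAM / DOWNSTREAM / GENIC from the signed distance.

    ``distance`` is the signed gap from :meth:`GeneIndex.nearest_gene`
    (negative: gene before the variant on the chromosome).  UPSTREAM means
    5' of the gene in the gene's own orientation.
    """
    if distance == 0:
        return "GENIC"
    if abs(distance) > threshold:
        return "INTERGENIC"
    variant_right_of_gene = distance < 0
    if (gene_strand == 1) != variant_right_of_gene:
        return "UPSTREAM"
    return "DOWNSTREAM"


@dataclass
class Location:
    """Where a variant span sits inside one transcript.

    Offsets are 1-based distances of the span's closest base from the
    containing element's 5' and 3' ends *in transcript orientation*; for a
    multi-base span, (off5, off5_far) is the covered range from the 5' end.
    """

    kind: str                 # EXONIC | INTRONIC | EXON_BOUNDARY_SPANNING
    element_index: int        # exon/intron index in transcript order
    off5: int = 0
    off5_far: int = 0
    off3: int = 0
    off3_far: int = 0


def _element_location(span: tuple[int, int], element: tuple[int, int],
                      strand: int, kind: str, index: int) -> Location:
    s, e = span
    gs, ge = element
    left_near, left_far = s - gs + 1, e - gs + 1
    right_near, right_far = ge - e + 1, ge - s + 1
    if strand == 1:
        return Location(kind, index, left_near, left_far, right_near, right_far)
    return Location(kind, index, right_near, right_far, left_near, left_far)


def locate_in_transcript(span: tuple[int, int],
                         transcript: Transcript) -> Location:
    """Locate a chromosomal span within a transcript's exon/intron chain."""
    s, e = span
    exons = transcript.exons
    n = len(exons)
    for i, exon in enumerate(exons):
        if exon.start <= s and e <= exon.end:
            idx = i if transcript.strand == 1 else n - 1 - i
            return _element_location(span, (exon.start, exon.end),
                                     transcript.strand, "EXONIC", idx)
    for i, (istart, iend) in enumerate(transcript.introns):
        if istart <= s and e <= iend:
            idx = i if transcript.strand == 1 else n - 2 - i
            return _element_location(span, (istart, iend),
                                     transcript.strand, "INTRONIC", idx)
    return Location("EXON_BOUNDARY_SPANNING", -1)


def splice_class(location: Location, transcript: Transcript,
                 config: Optional[ClassifierConfig] = None
                 ) -> set[FunctionalClass]:
    """Splice-window classes for a located span.

    Intronic offsets 1..2 from either intron end are ESSENTIAL_SPLICE_SITE,
    3..8 SPLICE_SITE; exonic offsets 1..3 from an exon end are SPLICE_SITE,
    counted only at exon-intron junctions (a transcript-terminal exon edge
    borders no splice site).
    """
    config = config or ClassifierConfig()
    classes: set[FunctionalClass] = set()
    if location.kind == "INTRONIC":
        ess = config.essential_intron_window
        lo, hi = config.splice_intron_window
        for near, far in ((location.off5, location.off5_far),
                          (location.off3, location.off3_far)):
            if near <= ess:
                classes.add(FC.ESSENTIAL_SPLICE_SITE)
            if near <= hi and far >= lo:
                classes.add(FC.SPLICE_SITE)
    elif location.kind == "EXONIC":
        n_exons = len(transcript.exons)
        w = config.splice_exon_window
        has_5p_junction = location.element_index > 0
        has_3p_junction = location.element_index < n_exons - 1
        if has_5p_junction and location.off5 <= w:
            classes.add(FC.SPLICE_SITE)
        if has_3p_junction and location.off3 <= w:
            classes.add(FC.SPLICE_SITE)
    return classes


def utr_class(span: tuple[int, int],
              transcript: Transcript) -> Optional[FunctionalClass]:
    """UTR / noncoding-transcript class for an exonic span.

    Returns WITHIN_NON_CODING_TRANSCRIPT for a transcript without a coding
    span; otherwise 5PRIME_UTR or 3PRIME_UTR when the span lies entirely
    outside the coding span, on the corresponding side in transcript
    orientation; None when the span touches the coding region.
    """
    if not transcript.is_coding:
        return FC.WITHIN_NON_CODING_TRANSCRIPT
    s, e = span
    if e < transcript.coding_start:
        return (FC.FIVE_PRIME_UTR if transcript.strand == 1
                else FC.THREE_PRIME_UTR)
    if s > transcript.coding_end:
        return (FC.THREE_PRIME_UTR if transcript.strand == 1
                else FC.FIVE_PRIME_UTR)
    return None


# ---------------------------------------------------------------------------
# coding-sequence machinery
# ---------------------------------------------------------------------------

def cds_segments(transcript: Transcript) -> list[tuple[int, int]]:
    """Exon pieces inside the coding span, in genome order."""
    if not transcript.is_coding:
        return []
    segments = []
    for exon in transcript.exons:
        lo = max(exon.start, transcript.coding_start)
        hi = min(exon.end, transcript.coding_end)
        if lo <= hi:
            segments.append((lo, hi))
    return segments


def cds_sequence(transcript: Transcript, genome) -> str:
    """Spliced coding sequence in transcript orientation."""
    parts = [genome.fetch(transcript.chromosome, lo, hi)
             for lo, hi in cds_segments(transcript)]
    seq = "".join(parts)
    return seq if transcript.strand == 1 else revcomp(seq)


def cds_index(transcript: Transcript, gpos: int) -> Optional[int]:
    """0-based index of a genome position in the transcript-oriented CDS."""
    segments = cds_segments(transcript)
    total = sum(hi - lo + 1 for lo, hi in segments)
    offset = 0
    for lo, hi in segments:
        if lo <= gpos <= hi:
            plus_index = offset + gpos - lo
            return plus_index if transcript.strand == 1 else total - 1 - plus_index
        offset += hi - lo + 1
    return None


def _transcript_oriented(seq: str, strand: int) -> str:
    return seq if strand == 1 else revcomp(seq)


def coding_effect(variant: VariantRecord, transcript: Transcript, genome,
                  code: GeneticCode, ref_offset: int = 1
                  ) -> Optional[TranscriptAnnotation]:
    """Codon-level consequence of a length-preserving variant.

    Requires the variant span to map fully onto the coding sequence.  The
    codon string carries an IUPAC symbol covering reference and alternative
    bases at each variable position; consecutive affected codons (MNPs) are
    joined with "/".  Stop / start codon changes replace the synonymous /
    nonsynonymous label.  Returns None when the span is not fully coding.
    """
    s = chrom_pos(variant.rel_start, ref_offset)
    e = chrom_pos(variant.rel_end, ref_offset)
    indices = [cds_index(transcript, g) for g in range(s, e + 1)]
    if any(i is None for i in indices):
        return None
    cds = cds_sequence(transcript, genome)
    if len(cds) % 3:
        logger.warning("%s: CDS length %d not divisible by 3; trailing "
                       "partial codon ignored", transcript.transcript_id, len(cds))
    idx_lo, idx_hi = min(indices), max(indices)
    ref_upper = (variant.ref_allele or "").upper()
    alts_t = [_transcript_oriented(a.upper(), transcript.strand)
              for a in variant.alt_alleles if a and a.upper() != ref_upper]
    if not alts_t or any(len(a) != (idx_hi - idx_lo + 1) for a in alts_t):
        return None
    n_codons = len(cds) // 3
    first_codon, last_codon = idx_lo // 3, min(idx_hi // 3, n_codons - 1)
    classes: set[FunctionalClass] = set()
    codon_displays: list[str] = []
    ref_aa_parts: list[str] = []
    alt_aa_parts: list[list[str]] = [[] for _ in alts_t]
    any_nonsyn = False
    stop_gained = stop_lost = start_lost = False
    for c in range(first_codon, last_codon + 1):
        ref_codon = cds[3 * c:3 * c + 3]
        alt_codons = []
        for alt in alts_t:
            codon = list(ref_codon)
            for k, idx in enumerate(range(idx_lo, idx_hi + 1)):
                if 3 * c <= idx < 3 * c + 3:
                    codon[idx - 3 * c] = alt[k]
            alt_codons.append("".join(codon))
        display = []
        for p in range(3):
            bases = {ref_codon[p]} | {ac[p] for ac in alt_codons}
            display.append(ref_codon[p] if len(bases) == 1 else iupac_symbol(bases))
        codon_displays.append("".join(display))
        ref_aa = code.translate(ref_codon)
        ref_aa_parts.append(_aa3(ref_aa))
        for j, ac in enumerate(alt_codons):
            alt_aa = code.translate(ac)
            alt_aa_parts[j].append(_aa3(alt_aa))
            if alt_aa != ref_aa:
                any_nonsyn = True
                if c == 0:
                    start_lost = True
            if code.is_stop(ac) and not code.is_stop(ref_codon):
                stop_gained = True
            if code.is_stop(ref_codon) and not code.is_stop(ac):
                stop_lost = True
    if stop_gained:
        classes.add(FC.STOP_GAINED)
    if stop_lost:
        classes.add(FC.STOP_LOST)
    if start_lost:
        classes.add(FC.START_LOST)
    if not classes:  # stop/start changes supersede the (non)synonymous label
        classes.add(FC.NON_SYNONYMOUS_CODING if any_nonsyn
                    else FC.SYNONYMOUS_CODING)
    alt_strings = []
    for parts in alt_aa_parts:
        joined = "".join(parts)
        if joined not in alt_strings:
            alt_strings.append(joined)
    return TranscriptAnnotation(
        transcript_id=transcript.transcript_id, strand=transcript.strand,
        classes=classes, codon="/".join(codon_displays),
        amino_acid="/".join(alt_strings), ref_amino_acid="".join(ref_aa_parts),
        region="CODING_REGION")


# ---------------------------------------------------------------------------
# start-gained scan
# ---------------------------------------------------------------------------

def transcript_sequence(transcript: Transcript, genome) -> str:
    """Spliced mature transcript sequence in transcript orientation."""
    seq = "".join(genome.fetch(transcript.chromosome, ex.start, ex.end)
                  for ex in transcript.exons)
    return _transcript_oriented(seq, transcript.strand)


def transcript_index(transcript: Transcript, gpos: int) -> Optional[int]:
    """0-based index of a genome position in the spliced transcript."""
    total = sum(ex.length for ex in transcript.exons)
    offset = 0
    for exon in transcript.exons:
        if exon.start <= gpos <= exon.end:
            plus = offset + gpos - exon.start
            return plus if transcript.strand == 1 else total - 1 - plus
        offset += exon.length
    return None


def start_gained_scan(variant: VariantRecord, transcript: Transcript, genome,
                      ref_offset: int = 1) -> bool:
    """Does the variant create an ATG absent from the reference context?

    Examines the edited spliced-transcript context around the variant (for
    SNPs/MNPs the three trinucleotide windows covering each changed
    position; for indels the locally re-built sequence).  Windows running
    past the transcript edge are skipped.  Intended for variants in the
    5' UTR of a coding transcript or in the exon of a noncoding transcript.
    """
    s = chrom_pos(variant.rel_start, ref_offset)
    e = chrom_pos(variant.rel_end, ref_offset)
    tx = transcript_sequence(transcript, genome)
    if variant.is_insertion:
        i = transcript_index(transcript, s)
        if i is None:
            return False
        # insertion sits between genome s-1 and s; in transcript coordinates
        # that gap is before index i on the plus strand, after it on minus
        gap = i if transcript.strand == 1 else i + 1
        lo, hi = gap, gap
    else:
        idx = [transcript_index(transcript, g) for g in range(s, e + 1)]
        if any(x is None for x in idx):
            return False
        lo, hi = min(idx), max(idx) + 1
    created = False
    for alt in variant.alt_alleles:
        alt_t = _transcript_oriented(alt.upper(), transcript.strand)
        window_lo = max(0, lo - 2)
        window_hi = min(len(tx), hi + 2)
        ref_ctx = tx[window_lo:window_hi]
        alt_ctx = (tx[window_lo:lo] + alt_t + tx[hi:window_hi])
        if "ATG" in alt_ctx and "ATG" not in ref_ctx:
            created = True
    return created


# ---------------------------------------------------------------------------
# indel consequences
# ---------------------------------------------------------------------------

def _junction_pairs(transcript: Transcript) -> list[tuple[str, int, int]]:
    """(kind, left_pos, right_pos) for each exon/intron junction.

    kind is "ACCEPTOR" for the junction at an exon's transcript-orientation
    start, "DONOR" at its end.
    """
    pairs = []
    for i, exon in enumerate(transcript.exons):
        if i > 0:  # junction on the genome-left side of the exon
            kind = "ACCEPTOR" if transcript.strand == 1 else "DONOR"
            pairs.append((kind, exon.start - 1, exon.start))
        if i < len(transcript.exons) - 1:  # genome-right side
            kind = "DONOR" if transcript.strand == 1 else "ACCEPTOR"
            pairs.append((kind, exon.end, exon.end + 1))
    return pairs


def indel_coding_effect(variant: VariantRecord, transcript: Transcript,
                        ref_offset: int = 1) -> set[FunctionalClass]:
    """Frame / complex classes for an indel relative to one transcript.

    Deletions spanning structure get the complex subclasses (DELETE_EXONS,
    MERGE_EXONS, ACCEPTOR, DONOR), which suppress the frame classes since
    the alternative splice pattern (hence protein) is not computable.  An
    indel contained in the coding part of an exon is FRAMEKEEP when the
    length change is a multiple of three, FRAMESHIFT otherwise.
    """
    s = chrom_pos(variant.rel_start, ref_offset)
    e = chrom_pos(variant.rel_end, ref_offset)
    classes: set[FunctionalClass] = set()
    if not variant.is_insertion:
        # deletion (or length-changing block substitution): structural checks
        covered_exon = any(s <= ex.start and ex.end <= e
                           for ex in transcript.exons)
        covered_intron = any(s <= istart and iend <= e
                             for istart, iend in transcript.introns)
        if covered_exon:
            classes.add(FC.DELETE_EXONS)
        elif covered_intron:
            classes.add(FC.MERGE_EXONS)
        else:
            for kind, left, right in _junction_pairs(transcript):
                if s <= left and right <= e:
                    classes.add(FC.ACCEPTOR if kind == "ACCEPTOR" else FC.DONOR)
        if classes:
            return classes
    # contained indel: frame consequence if it touches the CDS
    if not transcript.is_coding:
        return classes
    location = locate_in_transcript((s, e), transcript)
    if location.kind != "EXONIC":
        return classes
    overlaps_cds = not (e < transcript.coding_start or s > transcript.coding_end)
    if variant.is_insertion:
        overlaps_cds = transcript.coding_start <= s <= transcript.coding_end
    if not overlaps_cds:
        return classes
    ref_len = len(variant.ref_allele or "")
    for alt in variant.alt_alleles:
        delta = abs(len(alt) - ref_len)
        if delta == 0:
            continue
        classes.add(FC.FRAMEKEEP if delta % 3 == 0 else FC.FRAMESHIFT)
    # deletion overlapping the annotated start/stop codon
    segs = cds_segments(transcript)
    if segs and not variant.is_insertion and any(a == "" for a in variant.alt_alleles):
        total = sum(hi - lo + 1 for lo, hi in segs)
        start_codon = _cds_genome_positions(transcript, range(0, 3))
        stop_codon = _cds_genome_positions(transcript, range(total - 3, total))
        if any(s <= g <= e for g in start_codon):
            classes.add(FC.START_LOST)
        if any(s <= g <= e for g in stop_codon):
            classes.add(FC.STOP_LOST)
    return classes


def _cds_genome_positions(transcript: Transcript, indices) -> list[int]:
    """Genome positions of the given transcript-oriented CDS indices."""
    plus_order: list[int] = []
    for lo, hi in cds_segments(transcript):
        plus_order.extend(range(lo, hi + 1))
    if transcript.strand == -1:
        plus_order.reverse()
    return [plus_order[i] for i in indices if 0 <= i < len(plus_order)]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _annotate_transcript(variant: VariantRecord, transcript: Transcript,
                         genome, code: GeneticCode, vtype: VariantType,
                         config: ClassifierConfig, ref_offset: int
                         ) -> TranscriptAnnotation:
    s = chrom_pos(variant.rel_start, ref_offset)
    e = chrom_pos(variant.rel_end, ref_offset)
    ann = TranscriptAnnotation(transcript_id=transcript.transcript_id,
                               strand=transcript.strand)
    location = locate_in_transcript((s, e), transcript)
    ann.classes |= splice_class(location, transcript, config)
    if location.kind == "INTRONIC":
        ann.classes.add(FC.INTRONIC)
        ann.region = ("INTRONIC" if transcript.is_coding
                      else "WITHIN_NONCODING_TRANSCRIPT")
        if not transcript.is_coding:
            ann.classes.add(FC.WITHIN_NON_CODING_TRANSCRIPT)
        if vtype == VariantType.INDEL:
            # a deletion covering the intron exactly merges the exons
            ann.classes |= {c for c in
                            indel_coding_effect(variant, transcript, ref_offset)
                            if vtype in APPLICABILITY[c]}
    elif location.kind == "EXONIC":
        positional = utr_class((s, e), transcript)
        if positional is not None:
            ann.classes.add(positional)
            ann.region = {FC.FIVE_PRIME_UTR: "5PRIME_UTR",
                          FC.THREE_PRIME_UTR: "3PRIME_UTR",
                          FC.WITHIN_NON_CODING_TRANSCRIPT:
                              "WITHIN_NONCODING_TRANSCRIPT"}[positional]
        else:
            ann.region = "CODING_REGION"
        if vtype == VariantType.INDEL:
            ann.classes |= {c for c in
                            indel_coding_effect(variant, transcript, ref_offset)
                            if vtype in APPLICABILITY[c]}
        elif positional is None:
            effect = coding_effect(variant, transcript, genome, code, ref_offset)
            if effect is not None:
                ann.classes |= effect.classes
                ann.codon = effect.codon
                ann.amino_acid = effect.amino_acid
                ann.ref_amino_acid = effect.ref_amino_acid
        # potential start gained: 5' UTR of a coding gene or noncoding exon
        if positional in (FC.FIVE_PRIME_UTR, FC.WITHIN_NON_CODING_TRANSCRIPT):
            if start_gained_scan(variant, transcript, genome, ref_offset):
                ann.classes.add(FC.POTENTIAL_START_GAINED)
    else:  # spans an exon/intron boundary
        ann.region = "INTRONIC" if transcript.is_coding else \
            "WITHIN_NONCODING_TRANSCRIPT"
        if vtype == VariantType.INDEL:
            ann.classes |= {c for c in
                            indel_coding_effect(variant, transcript, ref_offset)
                            if vtype in APPLICABILITY[c]}
        if not ann.classes:
            ann.classes.add(FC.INTRONIC)
    return ann


def classify(variant: VariantRecord, gene_index: GeneIndex, genome,
             code: Optional[GeneticCode] = None,
             config: Optional[ClassifierConfig] = None,
             known_db=None, ref_offset: int = 1
             ) -> tuple[BasicRow, list[TranscriptAnnotation]]:
    """Full classification of one variant: one BasicRow plus per-transcript
    annotations (empty for intergenic/flanking or mismatched records)."""
    code = code or load_genetic_code()
    config = config or ClassifierConfig()
    s = chrom_pos(variant.rel_start, ref_offset)
    e = chrom_pos(variant.rel_end, ref_offset)
    row = BasicRow(name=variant.name, chromosome=variant.chromosome,
                   rel_start=variant.rel_start, rel_end=variant.rel_end,
                   chrom_start=s, chrom_end=e,
                   insertion=variant.is_insertion)

    if variant.ref_allele is None:  # pgSnp input: fill from the reference
        try:
            ref = genome.fetch(variant.chromosome, s, e)
            alts = [a for a in variant.alt_alleles if a.upper() != ref] \
                or variant.alt_alleles
            variant = VariantRecord(variant.name, variant.chromosome,
                                    variant.rel_start, variant.rel_end,
                                    alts[:3], ref)
        except Exception:
            row.status = "REF_MISMATCH"
            return row, []

    if not verify_ref(variant, genome, ref_offset):
        row.status = "REF_MISMATCH"
        return row, []

    vtype = classify_variant_type(variant.ref_allele or "",
                                  variant.alt_alleles,
                                  config.inversion_semantics)
    row.variant_type = vtype.value

    if known_db is not None:
        status, ids = known_db.status_of(variant, ref_offset)
        row.status, row.ids = status, ids
    else:
        row.status = "NOVEL"

    gene, distance = gene_index.nearest_gene(variant.chromosome, s, e)
    if gene is None:
        row.region = "INTERGENIC"
        row.distance = None
        return row, []
    row.nearest_gene = gene.gene_name or gene.gene_id
    row.distance = int(distance)

    if distance != 0:
        label = region_class(distance, gene.strand, config.distance_threshold)
        row.region = label
        ann = TranscriptAnnotation(
            transcript_id=gene.gene_name or gene.gene_id, strand=gene.strand,
            classes={FC(label)}, region=label)
        return row, [ann]

    annotations: list[TranscriptAnnotation] = []
    for g in gene_index.overlapping(variant.chromosome, s, e):
        for tx in g.transcripts:
            if e < tx.start or s > tx.end:
                continue
            try:
                annotations.append(_annotate_transcript(
                    variant, tx, genome, code, vtype, config, ref_offset))
            except Exception:  # pragma: no cover - defensive per-transcript guard
                logger.exception("annotation of %s against %s failed",
                                 variant.name, tx.transcript_id)
    if not annotations:
        # inside a gene span but outside its transcripts: intron-like
        annotations.append(TranscriptAnnotation(
            transcript_id=gene.gene_name or gene.gene_id, strand=gene.strand,
            classes={FC.INTRONIC}, region="INTRONIC"))

    regions = {a.region for a in annotations if a.region != NA}
    for label in REGION_PRECEDENCE:
        if label in regions:
            row.region = label
            break
    all_classes = set().union(*(a.classes for a in annotations))
    row.func_class = most_severe(all_classes, config.severity)
    return row, annotations


def most_severe(classes: set, severity: Optional[list] = None) -> str:
    """Most severe non-positional class, or "NONE"."""
    severity = severity or DEFAULT_SEVERITY
    for cls in severity:
        if cls in classes:
            return cls.value
    return "NONE"


def _severity_sort_key(cls: FunctionalClass, severity: list) -> tuple:
    order = severity + [c for c in FunctionalClass if c not in severity]
    return (order.index(cls), cls.value)


def detailed_rows_for(variant: VariantRecord,
                      annotations: list[TranscriptAnnotation],
                      row: BasicRow,
                      config: Optional[ClassifierConfig] = None
                      ) -> list[DetailedRow]:
    """One detailed row per (variant, transcript, class)."""
    config = config or ClassifierConfig()
    out: list[DetailedRow] = []
    if not annotations:  # mismatch or empty chromosome: a single NA row
        out.append(DetailedRow(
            name=variant.name, chromosome=variant.chromosome,
            rel_start=variant.rel_start, rel_end=variant.rel_end,
            alt_alleles=variant.alt_alleles, ref_allele=variant.ref_allele,
            func_class=NA if row.status == "REF_MISMATCH" else "INTERGENIC",
            transcript_id=NA, ids=row.ids))
        return out
    for ann in annotations:
        ordered = sorted(ann.classes,
                         key=lambda c: _severity_sort_key(c, config.severity))
        for cls in ordered:
            in_coding = cls in CODON_CLASSES
            out.append(DetailedRow(
                name=variant.name, chromosome=variant.chromosome,
                rel_start=variant.rel_start, rel_end=variant.rel_end,
                alt_alleles=variant.alt_alleles, ref_allele=variant.ref_allele,
                codon=ann.codon if in_coding else None,
                amino_acid=ann.amino_acid if in_coding else None,
                ref_amino_acid=ann.ref_amino_acid if in_coding else None,
                func_class=cls.value, transcript_id=ann.transcript_id,
                strand=ann.strand, ids=row.ids))
    return out


def annotate_variants(records: list[VariantRecord], gene_index: GeneIndex,
                      genome, code: Optional[GeneticCode] = None,
                      config: Optional[ClassifierConfig] = None,
                      known_db=None, ref_offset: int = 1,
                      annotation_table: Optional[dict] = None
                      ) -> tuple[list[BasicRow], list[DetailedRow]]:
    """Annotate a list of variants; the whole-pipeline entry point.

    ``annotation_table`` optionally maps (chromosome, position) to
    (conservation score, protein domain) pairs supplied by the user; those
    columns stay NA otherwise.  Exactly one basic row is produced per input
    record, in input order.
    """
    code = code or load_genetic_code()
    config = config or ClassifierConfig()
    basic: list[BasicRow] = []
    detailed: list[DetailedRow] = []
    for record in records:
        row, annotations = classify(record, gene_index, genome, code, config,
                                    known_db, ref_offset)
        rows = detailed_rows_for(record, annotations, row, config)
        if annotation_table:
            extra = annotation_table.get((record.chromosome, row.chrom_start))
            if extra:
                score, domain = extra
                for d in rows:
                    d.cons_score, d.protein_domain = score, domain
        basic.append(row)
        detailed.extend(rows)
    return basic, detailed
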