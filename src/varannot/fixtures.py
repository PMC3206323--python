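"""Deterministic synthetic genomes, annotations and truth-labelled variants.

Every classifier path is testable offline: the default fixture plants at
least one variant per functional class (all 21) on a small chromosome with
plus- and minus-strand coding genes, a noncoding gene and repeat tracts
for the indel-ambiguity machinery.  A second builder reproduces the
structural context of the documented worked example (two minus-strand
transcripts sharing a synonymous/nonsynonymous codon pair, an insertion
downstream of a neighbouring gene, an intronic inversion and heterozygous
SNP, and a coding 2 bp deletion), with synthetic identifiers.

Same seed, byte-identical outputs; all files are plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .gene_model import (Exon, GeneIndex, InMemoryGenome, Transcript,
                         revcomp)
from .variant_io import VariantRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# codons that are neither stop nor start in any of the supported codes
_FILLER_CODONS = ["GCA", "CTT", "GAA", "TCT", "GGA", "CCT", "AAA", "GAC"]

COMPLEMENT_MAP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# spec types
# ---------------------------------------------------------------------------

@dataclass
class GeneSpec:
    """Layout of one gene: exon chain, optional coding span, strand."""

    gene_id: str
    strand: int
    exons: list[tuple[int, int]]
    coding_span: Optional[tuple[int, int]] = None
    codon_overrides: dict[int, str] = field(default_factory=dict)
    transcript_ids: list[str] = field(default_factory=list)
    biotype: str = "coding"

    def cds_genome_positions(self) -> list[int]:
        """Genome positions of CDS bases, in transcript order."""
        if self.coding_span is None:
            return []
        lo, hi = self.coding_span
        positions: list[int] = []
        for es, ee in sorted(self.exons):
            s, e = max(es, lo), min(ee, hi)
            if s <= e:
                positions.extend(range(s, e + 1))
        return positions if self.strand == 1 else positions[::-1]


@dataclass
class PlantedVariant:
    """One planted variant plus its intended truth labels."""

    name: str
    rel_start: int
    rel_end: int
    alt_alleles: list[str]
    ref_allele: Optional[str]  # None: take from the generated genome
    classes: list[str]
    variant_type: str
    status: str = "NOVEL"
    region: Optional[str] = None
    ambiguity_group: Optional[str] = None


@dataclass
class KnownEntry:
    """One known-variants VCF record (VCF-style anchored alleles)."""

    rec_id: str
    pos: int
    ref: Optional[str]  # None: fill from genome
    alt: Optional[str]


@dataclass
class FixtureSpec:
    seed: int = 17
    chromosome: str = "chr1"
    length: int = 30_000
    genes: list[GeneSpec] = field(default_factory=list)
    motifs: list[tuple[int, str]] = field(default_factory=list)
    variants: list[PlantedVariant] = field(default_factory=list)
    known: list[KnownEntry] = field(default_factory=list)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    genome: InMemoryGenome
    gene_index: GeneIndex
    records: list[VariantRecord]
    truth: dict[str, PlantedVariant]
    known_db: object = None
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generation engine
# ---------------------------------------------------------------------------

def _random_background(seed: int, length: int) -> bytearray:
    rng = np.random.default_rng(seed)
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


class _GenomeBuilder:
    """Mutable chromosome under construction (1-based writes)."""

    def __init__(self, seed: int, length: int, start: int = 1) -> None:
        self.start = start
        self.seq = _random_background(seed, length)

    def write(self, pos: int, text: str) -> None:
        i = pos - self.start
        if i < 0 or i + len(text) > len(self.seq):
            raise ValueError(f"motif at {pos} exceeds chromosome bounds")
        self.seq[i:i + len(text)] = text.encode()

    def read(self, pos: int, length: int = 1) -> str:
        i = pos - self.start
        return self.seq[i:i + length].decode()

    def write_cds(self, gene: GeneSpec, rng: np.random.Generator) -> None:
        """Fill a gene's CDS with start + filler + overrides + stop codons."""
        positions = gene.cds_genome_positions()
        if not positions:
            return
        if len(positions) % 3:
            raise ValueError(f"{gene.gene_id}: CDS length {len(positions)} "
                             "not a multiple of 3")
        n_codons = len(positions) // 3
        codons = ["ATG"] + [
            _FILLER_CODONS[int(rng.integers(0, len(_FILLER_CODONS)))]
            for _ in range(n_codons - 2)] + ["TAA"]
        for idx, codon in gene.codon_overrides.items():
            codons[idx] = codon
        cds = "".join(codons)
        for i, gpos in enumerate(positions):
            base = cds[i]
            self.write(gpos, base if gene.strand == 1 else COMPLEMENT_MAP[base])


def _transcripts_of(gene: GeneSpec, chromosome: str) -> list[Transcript]:
    tx_ids = gene.transcript_ids or [f"{gene.gene_id}.t1"]
    exons = [Exon(s, e) for s, e in sorted(gene.exons)]
    start, end = exons[0].start, exons[-1].end
    cs, ce = gene.coding_span if gene.coding_span else (None, None)
    return [Transcript(
        transcript_id=tx_id, gene_id=gene.gene_id, chromosome=chromosome,
        start=start, end=end, strand=gene.strand, exons=list(exons),
        coding_start=cs, coding_end=ce, gene_name=gene.gene_id,
        biotype=gene.biotype if gene.coding_span else "noncoding")
        for tx_id in tx_ids]


def build_genome(spec: FixtureSpec, start: int = 1
                 ) -> tuple[InMemoryGenome, GeneIndex]:
    """Materialize the genome sequence and gene index of a spec."""
    builder = _GenomeBuilder(spec.seed, spec.length, start)
    rng = np.random.default_rng(spec.seed + 1)
    for gene in spec.genes:
        builder.write_cds(gene, rng)
    for pos, text in spec.motifs:
        builder.write(pos, text)
    genome = InMemoryGenome({spec.chromosome: builder.seq.decode()},
                            starts={spec.chromosome: start})
    transcripts = [tx for g in spec.genes
                   for tx in _transcripts_of(g, spec.chromosome)]
    return genome, GeneIndex.from_transcripts(transcripts)


def _materialize_variants(spec: FixtureSpec, genome: InMemoryGenome
                          ) -> list[VariantRecord]:
    records = []
    for pv in spec.variants:
        ref = pv.ref_allele
        if ref is None:
            ref = genome.fetch(spec.chromosome, pv.rel_start, pv.rel_end)
        alts = []
        for alt in pv.alt_alleles:
            # a planted SNP over random background may collide with the
            # reference base; rotate to the next base to keep it a variant
            if alt and ref and len(alt) == len(ref) == 1 \
                    and alt.upper() == ref.upper():
                alt = "ACGT"[("ACGT".index(ref.upper()) + 1) % 4]
            alts.append(alt)
        records.append(VariantRecord(
            name=pv.name, chromosome=spec.chromosome, rel_start=pv.rel_start,
            rel_end=pv.rel_end, alt_alleles=alts, ref_allele=ref))
    return records


def build_known_db(spec: FixtureSpec, genome: InMemoryGenome):
    """In-memory known-variants store from a spec's known entries."""
    from .known_variants import KnownVariantDB
    from .variant_io import _normalize_vcf_allele_pair
    db = KnownVariantDB(genome)
    for entry in spec.known:
        ref = entry.ref
        if ref is None:
            ref = genome.fetch(spec.chromosome, entry.pos, entry.pos)
        s, e, ref_a, alt_a = _normalize_vcf_allele_pair(entry.pos, ref,
                                                        entry.alt)
        if ref_a == "" or alt_a == "":
            db.add_indel(entry.rec_id, spec.chromosome, s, ref_a, alt_a,
                         genome)
        else:
            db.add_substitution(entry.rec_id, spec.chromosome, s, e, ref_a,
                                [alt_a])
    return db


# ---------------------------------------------------------------------------
# file writers (plain text only)
# ---------------------------------------------------------------------------

def write_fasta(genome: InMemoryGenome, chromosome: str, path: Path) -> None:
    first, last = genome.chromosome_span(chromosome)
    seq = genome.fetch(chromosome, first, last)
    with open(path, "w") as fh:
        fh.write(f">{chromosome}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")


def write_gff(spec: FixtureSpec, path: Path) -> None:
    lines = ["##gff-version 3"]
    for gene in spec.genes:
        exons = sorted(gene.exons)
        gs, ge = exons[0][0], exons[-1][1]
        strand = "+" if gene.strand == 1 else "-"
        lines.append("\t".join([
            spec.chromosome, "fixture", "gene", str(gs), str(ge), ".",
            strand, ".", f"ID={gene.gene_id};Name={gene.gene_id}"]))
        for tx in _transcripts_of(gene, spec.chromosome):
            ftype = "mRNA" if tx.is_coding else "transcript"
            lines.append("\t".join([
                spec.chromosome, "fixture", ftype, str(tx.start), str(tx.end),
                ".", strand, ".",
                f"ID={tx.transcript_id};Parent={gene.gene_id}"]))
            for i, exon in enumerate(tx.exons, 1):
                lines.append("\t".join([
                    spec.chromosome, "fixture", "exon", str(exon.start),
                    str(exon.end), ".", strand, ".",
                    f"ID={tx.transcript_id}.e{i};Parent={tx.transcript_id}"]))
            if tx.is_coding:
                for j, (cs, ce) in enumerate(_cds_pieces(gene), 1):
                    lines.append("\t".join([
                        spec.chromosome, "fixture", "CDS", str(cs), str(ce),
                        ".", strand, "0",
                        f"ID={tx.transcript_id}.c{j};Parent={tx.transcript_id}"]))
    path.write_text("\n".join(lines) + "\n")


def _cds_pieces(gene: GeneSpec) -> list[tuple[int, int]]:
    lo, hi = gene.coding_span
    out = []
    for es, ee in sorted(gene.exons):
        s, e = max(es, lo), min(ee, hi)
        if s <= e:
            out.append((s, e))
    return out


def write_variant_table(records: list[VariantRecord], path: Path) -> None:
    lines = ["Name\tChromosome\tRelStart\tRelEnd\tAltAlleles\tRefAllele"]
    for rec in records:
        alts = "/".join(a if a else "-" for a in rec.alt_alleles)
        ref = rec.ref_allele if rec.ref_allele else "-"
        lines.append(f"{rec.name}\t{rec.chromosome}\t{rec.rel_start}\t"
                     f"{rec.rel_end}\t{alts}\t{ref}")
    path.write_text("\n".join(lines) + "\n")


def write_known_vcf(spec: FixtureSpec, genome: InMemoryGenome,
                    path: Path) -> None:
    first, last = genome.chromosome_span(spec.chromosome)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={spec.chromosome},length={last}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for entry in spec.known:
        ref = entry.ref
        if ref is None:
            ref = genome.fetch(spec.chromosome, entry.pos, entry.pos)
        lines.append(f"{spec.chromosome}\t{entry.pos}\t{entry.rec_id}\t"
                     f"{ref}\t{entry.alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")


def write_truth(spec: FixtureSpec, path: Path) -> None:
    lines = ["Name\tClasses\tType\tStatus\tRegion\tAmbiguityGroup"]
    for pv in spec.variants:
        lines.append("\t".join([
            pv.name, ",".join(pv.classes), pv.variant_type, pv.status,
            pv.region or "NA", pv.ambiguity_group or "NA"]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the default 21-class fixture
# ---------------------------------------------------------------------------

def default_spec(seed: int = 17) -> FixtureSpec:
    """The default truth set: all 21 classes planted at least once.

    Layout (1-based, chromosome chr1, 30 kb):

    * repeat tracts at 3000 (poly-A x25), 3100 (GATx8), 3200 (GAGGCTx4)
    * GENE_P, plus strand, exons 10000-10199 / 10300-10499 / 10600-10799,
      CDS 10050-10750 (501 bp)
    * GENE_N, noncoding, exons 15000-15150 / 15250-15400
    * GENE_M, minus strand, mirror of GENE_P at 20000-20799
    """
    gene_p = GeneSpec(
        gene_id="GENE_P", strand=1,
        exons=[(10_000, 10_199), (10_300, 10_499), (10_600, 10_799)],
        coding_span=(10_050, 10_750),
        transcript_ids=["TXP1"],
        codon_overrides={17: "CTG", 20: "GCT", 23: "TAT"})
    gene_n = GeneSpec(
        gene_id="GENE_N", strand=1,
        exons=[(15_000, 15_150), (15_250, 15_400)],
        transcript_ids=["TXN1"])
    gene_m = GeneSpec(
        gene_id="GENE_M", strand=-1,
        exons=[(20_000, 20_199), (20_300, 20_499), (20_600, 20_799)],
        coding_span=(20_050, 20_750),
        transcript_ids=["TXM1"],
        codon_overrides={30: "GCT"})

    motifs = [
        # guarded repeat tracts (left/right guards differ from the unit)
        (2_999, "C" + "A" * 25 + "G"),
        (3_099, "C" + "GAT" * 8 + "C"),
        (3_199, "T" + "GAGGCT" * 4 + "T"),
        # potential-start-gained context in the 5' UTR of GENE_P:
        # ref CACGC; C->T at 10031 creates ATG in the middle window
        (10_029, "CACGC"),
        # MNP / inversion reference contexts deep in intron 1 of GENE_P
        (10_255, "AC"),
        (10_260, "TTAG"),
    ]

    snp = lambda name, pos, alt, classes, status="NOVEL", region=None: \
        PlantedVariant(name, pos, pos, [alt], None, classes, "SNP",
                       status, region)

    variants = [
        snp("v_intergenic", 2_000, "A", ["INTERGENIC"], region="INTERGENIC"),
        snp("v_upstream", 9_000, "C", ["UPSTREAM"], region="UPSTREAM"),
        snp("v_downstream", 12_000, "G", ["DOWNSTREAM"], region="DOWNSTREAM"),
        snp("v_5utr", 10_020, "T", ["5PRIME_UTR"], region="5PRIME_UTR"),
        snp("v_psg", 10_031, "T", ["5PRIME_UTR", "POTENTIAL_START_GAINED"],
            region="5PRIME_UTR"),
        snp("v_3utr", 10_770, "A", ["3PRIME_UTR"], region="3PRIME_UTR"),
        snp("v_syn", 10_103, "A", ["SYNONYMOUS_CODING"], status="KNOWN",
            region="CODING_REGION"),
        snp("v_nonsyn", 10_111, "A", ["NON_SYNONYMOUS_CODING"],
            status="ALTERNATIVE", region="CODING_REGION"),
        snp("v_stopgain", 10_121, "A", ["STOP_GAINED"], region="CODING_REGION"),
        snp("v_stoplost", 10_750, "C", ["STOP_LOST"], region="CODING_REGION"),
        snp("v_startlost", 10_052, "A", ["START_LOST"], region="CODING_REGION"),
        snp("v_intronic", 10_250, "A", ["INTRONIC"], region="INTRONIC"),
        snp("v_esssplice", 10_200, "A", ["ESSENTIAL_SPLICE_SITE", "INTRONIC"],
            region="INTRONIC"),
        snp("v_splice_i", 10_205, "A", ["SPLICE_SITE", "INTRONIC"],
            region="INTRONIC"),
        snp("v_splice_e", 10_498, "A", ["SPLICE_SITE"], region="CODING_REGION"),
        snp("v_noncoding", 15_100, "A", ["WITHIN_NON_CODING_TRANSCRIPT"],
            region="WITHIN_NONCODING_TRANSCRIPT"),
        PlantedVariant("v_mnp", 10_255, 10_256, ["GT"], None,
                       ["INTRONIC"], "MNP", region="INTRONIC"),
        PlantedVariant("v_inv", 10_260, 10_263, ["GATT"], None,
                       ["INTRONIC"], "INVERSION", region="INTRONIC"),
        PlantedVariant("v_framekeep", 10_400, 10_402, [""], None,
                       ["FRAMEKEEP"], "INDEL", region="CODING_REGION"),
        PlantedVariant("v_frameshift", 10_410, 10_411, [""], None,
                       ["FRAMESHIFT"], "INDEL", region="CODING_REGION"),
        PlantedVariant("v_ins_cds", 10_450, 10_450, ["TT"], "",
                       ["FRAMESHIFT"], "INDEL", region="CODING_REGION"),
        PlantedVariant("v_ins_3utr", 10_775, 10_775, ["GGG"], "",
                       ["3PRIME_UTR"], "INDEL", region="3PRIME_UTR"),
        PlantedVariant("v_delexon", 10_290, 10_510, [""], None,
                       ["DELETE_EXONS"], "INDEL"),
        PlantedVariant("v_mergeexon", 10_500, 10_599, [""], None,
                       ["MERGE_EXONS"], "INDEL", region="INTRONIC"),
        PlantedVariant("v_acceptor", 10_295, 10_305, [""], None,
                       ["ACCEPTOR"], "INDEL"),
        PlantedVariant("v_donor", 10_495, 10_505, [""], None,
                       ["DONOR"], "INDEL"),
        # minus-strand coding gene: codon 30 is GCT (Ala) in transcript
        # orientation; the genome-plus middle base is complement(C)=G at
        # the codon's middle genome position
        snp("v_m_nonsyn", 0, "", ["NON_SYNONYMOUS_CODING"],
            region="CODING_REGION"),  # placeholder, fixed below
        snp("v_m_upstream", 21_500, "A", ["UPSTREAM"], region="UPSTREAM"),
        # ambiguous single-A deletions inside the poly-A tract
        PlantedVariant("v_polyA_1", 3_005, 3_005, [""], None, ["INTERGENIC"],
                       "INDEL", status="KNOWN", region="INTERGENIC",
                       ambiguity_group="polyA"),
        PlantedVariant("v_polyA_2", 3_010, 3_010, [""], None, ["INTERGENIC"],
                       "INDEL", status="KNOWN", region="INTERGENIC",
                       ambiguity_group="polyA"),
        PlantedVariant("v_polyA_3", 3_015, 3_015, [""], None, ["INTERGENIC"],
                       "INDEL", status="KNOWN", region="INTERGENIC",
                       ambiguity_group="polyA"),
        PlantedVariant("v_polyA_4", 3_020, 3_020, [""], None, ["INTERGENIC"],
                       "INDEL", status="KNOWN", region="INTERGENIC",
                       ambiguity_group="polyA"),
    ]

    # v_m_nonsyn: middle base of minus-strand codon 30
    m_positions = gene_m.cds_genome_positions()
    mid = m_positions[30 * 3 + 1]
    for pv in variants:
        if pv.name == "v_m_nonsyn":
            pv.rel_start = pv.rel_end = mid
            # transcript C -> A gives GAT (Asp): genome-plus alt is comp(A)=T
            pv.alt_alleles = ["T"]

    known = [
        KnownEntry("kv_syn", 10_103, "G", "A"),
        KnownEntry("kv_alt", 10_111, "C", "G"),
        # two redundant placements of the same single-A deletion
        KnownEntry("kv_polyA_a", 2_999, "CA", "C"),
        KnownEntry("kv_polyA_b", 3_007, "AA", "A"),
    ]

    return FixtureSpec(seed=seed, genes=[gene_p, gene_n, gene_m],
                       motifs=motifs, variants=variants, known=known)


def make_fixture(spec: Optional[FixtureSpec] = None,
                 outdir: Optional[Path] = None) -> FixtureBundle:
    """Materialize a fixture spec; optionally write its files.

    Files (when ``outdir`` is given): genome.fa, genes.gff3, variants.tsv,
    known.vcf, truth.tsv — all plain text.
    """
    spec = spec or default_spec()
    genome, gene_index = build_genome(spec)
    records = _materialize_variants(spec, genome)
    bundle = FixtureBundle(spec=spec, genome=genome, gene_index=gene_index,
                           records=records,
                           truth={pv.name: pv for pv in spec.variants},
                           known_db=build_known_db(spec, genome))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff": outdir / "genes.gff3",
            "variants": outdir / "variants.tsv",
            "known": outdir / "known.vcf",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(genome, spec.chromosome, paths["fasta"])
        write_gff(spec, paths["gff"])
        write_variant_table(records, paths["variants"])
        write_known_vcf(spec, genome, paths["known"])
        write_truth(spec, paths["truth"])
        bundle.paths = paths
    return bundle


# ---------------------------------------------------------------------------
# worked-example context (documented input of seven variants)
# ---------------------------------------------------------------------------

#: The seven-variant input table of the worked example, six-column format.
WORKED_EXAMPLE_TABLE = """\
Name	Chromosome	RelStart	RelEnd	AltAlleles	RefAllele
var1	12	12483171	12483171	C	G
var2	12	12483200	12483200	G	T
var3	12	12506184	12506184	T	—
var4	12	12527105	12527108	GATT	TTAG
var5	12	12550471	12550471	A/G	T
var6	12	12588583	12588583	A	C
var7	12	12588586	12588587	—	CA
"""

_WE_START = 12_480_001
_WE_LENGTH = 120_000


def worked_example(seed: int = 11) -> FixtureBundle:
    """Synthetic genome + annotation reproducing the worked example.

    Three genes on chromosome "12" (region held in memory with a
    coordinate offset): a minus-strand two-transcript coding gene hosting
    a synonymous SNP (codon GCS, Ala/Ala) and a nonsynonymous SNP (codon
    MAA, Lys->Gln); a neighbouring minus-strand gene with an insertion
    316 bp downstream of it; and a plus-strand two-transcript gene with an
    intronic inversion, an intronic heterozygous SNP, a nonsynonymous SNP
    (codon TMC, Ser->Tyr) and a coding 2 bp frameshift deletion.
    """
    gene_a = GeneSpec(
        gene_id="GENE_A", strand=-1,
        exons=[(12_483_000, 12_483_400)],
        coding_span=(12_483_105, 12_483_266),
        transcript_ids=["TXA1", "TXA2"],
        codon_overrides={22: "AAA", 31: "GCC"})
    gene_b = GeneSpec(
        gene_id="GENE_B", strand=-1,
        exons=[(12_506_500, 12_508_000)],
        transcript_ids=["TXB1"])
    gene_c = GeneSpec(
        gene_id="GENE_C", strand=1,
        exons=[(12_526_000, 12_526_200), (12_588_000, 12_589_000)],
        coding_span=(12_588_102, 12_588_731),
        transcript_ids=["TXC1", "TXC2"],
        codon_overrides={160: "TCC", 161: "CCA"})

    motifs = [
        (12_527_105, "TTAG"),      # intronic inversion context
        (12_550_471, "T"),         # intronic heterozygous SNP reference base
        (12_506_182, "ATTTG"),     # T-run: the known insertion is ambiguous
    ]

    spec = FixtureSpec(
        seed=seed, chromosome="12", length=_WE_LENGTH,
        genes=[gene_a, gene_b, gene_c], motifs=motifs,
        variants=[], known=[
            KnownEntry("rsA1", 12_483_171, "G", "C"),
            KnownEntry("rsB1", 12_506_182, "A", "AT"),
            KnownEntry("rsB2", 12_506_184, "T", "TT"),
            KnownEntry("rsC1", 12_588_583, "C", "A"),
        ])
    builder_genome, gene_index = build_genome(spec, start=_WE_START)
    from .variant_io import parse_variant_table
    records, errors = parse_variant_table(WORKED_EXAMPLE_TABLE)
    assert not errors
    return FixtureBundle(spec=spec, genome=builder_genome,
                         gene_index=gene_index, records=records, truth={},
                         known_db=build_known_db(spec, builder_genome))


def single_gene_scan_fixture(seed: int = 5, length: int = 20_000,
                             gene_span: tuple[int, int] = (8_000, 9_000)
                             ) -> tuple[InMemoryGenome, GeneIndex, str]:
    """A chromosome with exactly one (coding, single-exon) gene.

    Used for exhaustive distance scans of the UPSTREAM/DOWNSTREAM ->
    INTERGENIC flip.  The coding span length is trimmed to a multiple of 3.
    """
    gs, ge = gene_span
    cds_len = (ge - gs - 99) // 3 * 3
    gene = GeneSpec(gene_id="GENE_S", strand=1, exons=[(gs, ge)],
                    coding_span=(gs + 50, gs + 50 + cds_len - 1),
                    transcript_ids=["TXS1"])
    spec = FixtureSpec(seed=seed, chromosome="chrS", length=length,
                       genes=[gene])
    genome, index = build_genome(spec)
    return genome, index, spec.chromosome
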