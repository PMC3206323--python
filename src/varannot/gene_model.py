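"""Gene structure, reference-sequence access and coordinate mapping.

Transcript models are loaded from GFF3 or BED12 into a :class:`GeneIndex`
backed by per-chromosome interval trees.  The reference genome is exposed
through a tiny accessor protocol (:meth:`fetch`) with two implementations:
an in-memory genome (used by the synthetic fixtures and the tests) and a
FASTA-file genome backed by :mod:`pyfaidx`.

Coordinates are 1-based with inclusive ends throughout, the convention of
GFF3 and of the six-column variant table.  BED input (0-based, half-open)
is converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gffutils
import pyfaidx
from intervaltree import IntervalTree

logger = logging.getLogger("varannot")

COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Exon:
    """One exon, 1-based inclusive chromosome coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """A transcript: exon chain, optional coding span, strand.

    ``coding_start``/``coding_end`` are chromosome coordinates (so
    coding_start <= coding_end on both strands); ``strand`` is +1 or -1.
    A transcript without a coding span is noncoding.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: int
    exons: list[Exon] = field(default_factory=list)
    coding_start: Optional[int] = None
    coding_end: Optional[int] = None
    gene_name: str = ""
    biotype: str = "coding"

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}")
        if (self.coding_start is None) != (self.coding_end is None):
            raise ValueError("coding_start/coding_end must be set together")
        if self.coding_start is not None and self.coding_start > self.coding_end:
            raise ValueError("coding_start > coding_end")
        if self.coding_start is None:
            self.biotype = "noncoding" if self.biotype == "coding" else self.biotype

    @property
    def is_coding(self) -> bool:
        return self.coding_start is not None

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Intron spans (1-based inclusive), in genome order."""
        return [(a.end + 1, b.start - 1)
                for a, b in zip(self.exons, self.exons[1:])]

    def exons_in_transcript_order(self) -> list[Exon]:
        return self.exons if self.strand == 1 else list(reversed(self.exons))


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    strand: int
    transcripts: list[Transcript] = field(default_factory=list)


class GeneIndex:
    """Per-chromosome interval index over genes and their transcripts."""

    def __init__(self) -> None:
        self._genes: dict[str, Gene] = {}
        self._trees: dict[str, IntervalTree] = {}

    # -- construction -------------------------------------------------
    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene id {gene.gene_id}")
        self._genes[gene.gene_id] = gene
        tree = self._trees.setdefault(gene.chromosome, IntervalTree())
        # intervaltree is half-open; store [start, end+1)
        tree[gene.start:gene.end + 1] = gene.gene_id

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[Transcript]) -> "GeneIndex":
        by_gene: dict[str, list[Transcript]] = {}
        for tx in transcripts:
            by_gene.setdefault(tx.gene_id, []).append(tx)
        index = cls()
        for gene_id, txs in by_gene.items():
            gene = Gene(
                gene_id=gene_id,
                gene_name=txs[0].gene_name or gene_id,
                chromosome=txs[0].chromosome,
                start=min(t.start for t in txs),
                end=max(t.end for t in txs),
                strand=txs[0].strand,
                transcripts=sorted(txs, key=lambda t: t.transcript_id),
            )
            index.add_gene(gene)
        return index

    # -- queries ------------------------------------------------------
    @property
    def genes(self) -> list[Gene]:
        return sorted(self._genes.values(), key=lambda g: (g.chromosome, g.start, g.gene_id))

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def overlapping(self, chromosome: str, start: int, end: int) -> list[Gene]:
        """All genes whose span intersects [start, end] (1-based incl.)."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        genes = [self._genes[h.data] for h in hits]
        return sorted(genes, key=lambda g: (g.start, g.gene_id))

    def nearest_gene(self, chromosome: str, start: int,
                     end: int) -> tuple[Optional[Gene], float]:
        """Nearest gene and signed distance.

        Distance is 0 when [start, end] overlaps the gene span; otherwise
        the bp gap to the closest gene boundary, negative when the gene
        lies entirely before the variant on the chromosome, positive when
        entirely after.  Ties break to the smaller gene start, then the
        lexicographically smaller gene id.  Returns (None, inf) when the
        chromosome holds no genes.
        """
        overlapping = self.overlapping(chromosome, start, end)
        if overlapping:
            return overlapping[0], 0
        tree = self._trees.get(chromosome)
        if not tree:
            return None, float("inf")
        best: Optional[tuple[int, int, str, Gene, int]] = None
        for iv in tree:
            gene = self._genes[iv.data]
            if gene.end < start:          # gene before the variant
                dist, signed = start - gene.end, -(start - gene.end)
            else:                         # gene after the variant
                dist, signed = gene.start - end, gene.start - end
            key = (dist, gene.start, gene.gene_id)
            if best is None or key < (best[0], best[1], best[2]):
                best = (dist, gene.start, gene.gene_id, gene, signed)
        assert best is not None
        return best[3], best[4]


# ---------------------------------------------------------------------------
# reference genome accessors
# ---------------------------------------------------------------------------

class ReferenceBoundsError(ValueError):
    """A slice request fell outside the available sequence."""


class InMemoryGenome:
    """Reference genome held as strings, optionally coordinate-offset.

    ``starts`` gives, per chromosome, the 1-based chromosome coordinate of
    the first stored base; this allows a fixture to model a short region of
    a large chromosome without materialising the prefix.
    """

    def __init__(self, sequences: dict[str, str],
                 starts: Optional[dict[str, int]] = None) -> None:
        self._seq = {c: s.upper() for c, s in sequences.items()}
        self._starts = dict(starts or {})

    def chromosome_span(self, chromosome: str) -> tuple[int, int]:
        if chromosome not in self._seq:
            raise ReferenceBoundsError(f"unknown chromosome {chromosome!r}")
        first = self._starts.get(chromosome, 1)
        return first, first + len(self._seq[chromosome]) - 1

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        first, last = self.chromosome_span(chromosome)
        if start < first or end > last or start > end:
            raise ReferenceBoundsError(
                f"{chromosome}:{start}-{end} outside available {first}-{last}")
        return self._seq[chromosome][start - first:end - first + 1]


class FastaGenome:
    """Reference genome backed by a FASTA file via pyfaidx."""

    def __init__(self, path: str) -> None:
        self._fasta = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)

    def chromosome_span(self, chromosome: str) -> tuple[int, int]:
        if chromosome not in self._fasta:
            raise ReferenceBoundsError(f"unknown chromosome {chromosome!r}")
        return 1, len(self._fasta[chromosome])

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        first, last = self.chromosome_span(chromosome)
        if start < first or end > last or start > end:
            raise ReferenceBoundsError(
                f"{chromosome}:{start}-{end} outside available {first}-{last}")
        return str(self._fasta[chromosome][start - 1:end])


def fetch_slice(genome, chromosome: str, start: int, end: int) -> str:
    """Uppercase genome substring, 1-based inclusive; errors on bounds."""
    return genome.fetch(chromosome, start, end)


def chrom_pos(rel_pos: int, ref_offset: int = 1) -> int:
    """Map a position relative to the reference slice onto the chromosome.

    ``ref_offset`` is the 1-based chromosomal position of the reference
    sequence's first base, so ``ref_offset == 1`` is the identity.
    """
    if rel_pos < 1:
        raise ValueError(f"relative position must be >= 1, got {rel_pos}")
    return rel_pos + ref_offset - 1


def verify_ref(variant, genome, ref_offset: int = 1) -> bool:
    """Check the declared reference allele against the genome.

    Insertions (empty reference allele) verify trivially.  A mismatch is a
    data condition, not an error: the caller marks the record REF_MISMATCH
    and keeps it in the output with NA fields.
    """
    if not variant.ref_allele:
        return True
    start = chrom_pos(variant.rel_start, ref_offset)
    end = chrom_pos(variant.rel_end, ref_offset)
    try:
        observed = genome.fetch(variant.chromosome, start, end)
    except ReferenceBoundsError:
        return False
    return observed == variant.ref_allele.upper()


# ---------------------------------------------------------------------------
# annotation loaders
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "miRNA", "lnc_RNA",
                     "snoRNA", "snRNA", "rRNA", "tRNA", "pseudogenic_transcript"}


def load_gff(path: str) -> GeneIndex:
    """Load gene/transcript/exon/CDS structure from a GFF3 file.

    CDS child features define the coding span; transcripts without CDS are
    noncoding.  Orphan exons (no resolvable transcript parent) are dropped
    with a warning.  Feature order in the file does not matter.
    """
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    transcripts: list[Transcript] = []
    gene_names: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [g.id])[0]
        gene_names[g.id] = name
    for ftype in sorted(_TRANSCRIPT_TYPES):
        for t in db.features_of_type(ftype):
            exons = [Exon(c.start, c.end) for c in db.children(t, featuretype="exon")]
            cds = [(c.start, c.end) for c in db.children(t, featuretype="CDS")]
            if not exons:
                logger.warning("transcript %s has no exons; skipped", t.id)
                continue
            gene_id = t.attributes.get("Parent", [t.id])[0]
            coding_start = min(c[0] for c in cds) if cds else None
            coding_end = max(c[1] for c in cds) if cds else None
            biotype = "coding" if cds else "noncoding"
            if ftype == "miRNA":
                biotype = "miRNA"
            transcripts.append(Transcript(
                transcript_id=t.id, gene_id=gene_id, chromosome=t.seqid,
                start=t.start, end=t.end, strand=1 if t.strand != "-" else -1,
                exons=exons, coding_start=coding_start, coding_end=coding_end,
                gene_name=gene_names.get(gene_id, gene_id), biotype=biotype))
    # warn on exons whose parent is not a known transcript
    known = {t.transcript_id for t in transcripts}
    for e in db.features_of_type("exon"):
        parents = e.attributes.get("Parent", [])
        if parents and not any(p in known for p in parents):
            logger.warning("orphan exon %s:%d-%d dropped", e.seqid, e.start, e.end)
    return GeneIndex.from_transcripts(transcripts)


def load_bed(path: str) -> GeneIndex:
    """Load transcript structure from a BED12 file.

    BED is 0-based half-open; converted to 1-based inclusive.  thickStart ==
    thickEnd marks a noncoding transcript.  Each BED line becomes one
    transcript; the name column doubles as gene id unless it carries a
    ``gene:tx`` pair.
    """
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                logger.warning("BED line %d: %d columns, need 12; skipped",
                               lineno, len(f))
                continue
            chrom, chrom_start, chrom_end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = -1 if f[5] == "-" else 1
            thick_start, thick_end = int(f[6]), int(f[7])
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if not (len(sizes) == len(offsets) == block_count):
                logger.warning("BED line %d: block count mismatch; skipped", lineno)
                continue
            exons = [Exon(chrom_start + off + 1, chrom_start + off + size)
                     for off, size in zip(offsets, sizes)]
            if thick_start == thick_end:
                coding_start = coding_end = None
            else:
                coding_start, coding_end = thick_start + 1, thick_end
            gene_id, _, tx_id = name.partition(":")
            tx_id = tx_id or name
            transcripts.append(Transcript(
                transcript_id=tx_id, gene_id=gene_id, chromosome=chrom,
                start=chrom_start + 1, end=chrom_end, strand=strand,
                exons=exons, coding_start=coding_start, coding_end=coding_end,
                gene_name=gene_id))
    return GeneIndex.from_transcripts(transcripts)
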