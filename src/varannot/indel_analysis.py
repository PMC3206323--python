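"""Indel normalization, equivalence grouping and characterization.

An insertion or deletion inside a repeat tract has many placements that
all produce the same edited sequence; public databases frequently carry
several records for what is physically one indel.  Canonicalizing every
indel to its left-most equivalent placement makes equivalence a simple
equality test, groups redundant annotations, and gives known-variant
matching a placement-independent key.

Also here: the repeat period of an indel sequence, the evolutionary-genesis
flags (duplication of an adjacent flank, reversal of a flank, shifted
element) and the 13 bp transposon flank check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .gene_model import ReferenceBoundsError

TRANSPOSON_FLANK = 13  # bp of flanking sequence scanned for a copy
SHIFT_SCAN_WINDOW = 50  # default "shifting element" search window, bp


@dataclass(frozen=True)
class CanonicalIndel:
    """Left-most equivalent placement of a pure insertion or deletion.

    ``canonical_pos`` is 1-based: for a deletion the first deleted base;
    for an insertion the base *before which* the sequence is inserted.
    Two indels are the same physical edit iff their CanonicalIndels are
    equal.
    """

    chromosome: str
    canonical_pos: int
    op: str  # "INSERTION" | "DELETION"
    sequence: str


@dataclass
class GenesisReport:
    """Evolutionary-genesis characterization of one indel.

    Flags are independent; any may be None when the required flank runs
    off the end of the available sequence.
    """

    is_duplication: Optional[bool] = None
    is_inversion_of_flank: Optional[bool] = None
    is_shift: Optional[bool] = None
    period_length: int = 0
    transposon_flag: Optional[bool] = None


@dataclass
class IndelGroup:
    """One equivalence class of indel records."""

    canonical: CanonicalIndel
    members: list = field(default_factory=list)  # the original records


def _as_pure_indel(ref_allele: str, alt_allele: str) -> tuple[str, str, int]:
    """Trim shared leading bases; return (op, sequence, pos_shift).

    Returns the operation, the inserted/deleted sequence, and how many
    bases were trimmed from the left (the caller advances its position by
    that amount).  Raises ValueError if the pair is not a pure indel after
    trimming.
    """
    ref, alt = ref_allele.upper(), alt_allele.upper()
    shift = 0
    while ref and alt and ref[0] == alt[0]:
        ref, alt, shift = ref[1:], alt[1:], shift + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if ref and alt:
        raise ValueError(
            f"not a pure insertion/deletion: ref {ref_allele!r} alt {alt_allele!r}")
    if not ref and not alt:
        raise ValueError("empty edit: ref equals alt")
    return ("DELETION", ref, shift) if ref else ("INSERTION", alt, shift)


def canonicalize(chromosome: str, pos: int, ref_allele: str, alt_allele: str,
                 genome) -> CanonicalIndel:
    """Left-align an indel to its canonical placement.

    ``pos`` is the 1-based position of the first base of ``ref_allele``
    (for a deletion) or the base before which ``alt_allele`` is inserted
    (for an insertion with empty ``ref_allele``).  The indel is shifted
    left one base at a time while the edited chromosome is unchanged:
    a placement can move from p to p-1 iff the base at p-1 equals the last
    base of the (rotated) indel sequence.  Idempotent by construction.

    Raises ValueError when a non-empty ``ref_allele`` disagrees with the
    genome at ``pos``.
    """
    op, seq, shift = _as_pure_indel(ref_allele or "", alt_allele or "")
    pos += shift
    if op == "DELETION":
        observed = genome.fetch(chromosome, pos, pos + len(seq) - 1)
        if observed != seq:
            raise ValueError(
                f"reference mismatch at {chromosome}:{pos}: "
                f"declared {seq!r}, genome has {observed!r}")
    first, _ = genome.chromosome_span(chromosome)
    while pos > first:
        try:
            prev = genome.fetch(chromosome, pos - 1, pos - 1)
        except ReferenceBoundsError:
            break
        if prev != seq[-1]:
            break
        pos -= 1
        seq = prev + seq[:-1]
    return CanonicalIndel(chromosome, pos, op, seq)


def group_equivalent(indels: list, genome) -> list[IndelGroup]:
    """Partition indel records by canonical equality.

    ``indels`` is a list of objects (or tuples) carrying chromosome, pos,
    ref_allele and alt_allele; tuples are ``(name, chromosome, pos, ref,
    alt)``.  Grouping is per chromosome.  Records that fail to
    canonicalize (reference mismatch, not a pure indel) are skipped.
    Groups are returned sorted by (chromosome, canonical position), each
    group's members in input order; groups of size > 1 are the ambiguous
    annotations.
    """
    groups: dict[CanonicalIndel, IndelGroup] = {}
    for rec in indels:
        if isinstance(rec, tuple):
            name, chrom, pos, ref, alt = rec
        else:
            name, chrom, pos, ref, alt = (rec.name, rec.chromosome,
                                          rec.rel_start, rec.ref_allele,
                                          rec.alt_alleles[0])
        try:
            key = canonicalize(chrom, pos, ref, alt, genome)
        except (ValueError, ReferenceBoundsError):
            continue
        groups.setdefault(key, IndelGroup(canonical=key)).members.append(name)
    return sorted(groups.values(),
                  key=lambda g: (g.canonical.chromosome, g.canonical.canonical_pos,
                                 g.canonical.op, g.canonical.sequence))


def period_length(sequence: str) -> int:
    """Smallest period p >= 1 with sequence[i] == sequence[i+p] for all i.

    The string-combinatorics period: 1 for a homopolymer, |unit| for a
    clean tandem repeat of a primitive unit, len(sequence) when there is
    no internal repeat structure.
    """
    if not sequence:
        raise ValueError("empty sequence has no period")
    n = len(sequence)
    for p in range(1, n + 1):
        if all(sequence[i] == sequence[i + p] for i in range(n - p)):
            return p
    return n  # unreachable; p == n always satisfies the loop


def transposon_flag(chromosome: str, canonical_pos: int, op: str,
                    sequence: str, genome) -> Optional[bool]:
    """13 bp flank check for a potential transposon.

    True iff the indel sequence, or its reversal, occurs as a substring of
    the 13 bp of flanking sequence on either side; sequences longer than
    13 bp compare their first/last 13 bp.  None when both flanks are
    truncated by the chromosome edge to less than the probe length.
    """
    probe_left = sequence[:TRANSPOSON_FLANK]
    probe_right = sequence[-TRANSPOSON_FLANK:]
    left_of, right_of = _flank_anchors(canonical_pos, op, len(sequence))
    first, last = genome.chromosome_span(chromosome)
    flanks: list[str] = []
    lo = max(first, left_of - TRANSPOSON_FLANK + 1)
    if lo <= left_of:
        flanks.append(genome.fetch(chromosome, lo, left_of))
    hi = min(last, right_of + TRANSPOSON_FLANK - 1)
    if right_of <= hi:
        flanks.append(genome.fetch(chromosome, right_of, hi))
    usable = [f for f in flanks if f]
    if not usable:
        return None
    for flank in usable:
        for probe in {probe_left, probe_right, probe_left[::-1], probe_right[::-1]}:
            if len(probe) <= len(flank) and probe in flank:
                return True
    return False


def _flank_anchors(canonical_pos: int, op: str, seq_len: int) -> tuple[int, int]:
    """Last base of the left flank and first base of the right flank."""
    if op == "DELETION":
        return canonical_pos - 1, canonical_pos + seq_len
    return canonical_pos - 1, canonical_pos  # insertion sits in the gap


def genesis(indel: CanonicalIndel, genome,
            shift_window: int = SHIFT_SCAN_WINDOW) -> GenesisReport:
    """Evolutionary-genesis flags and repeat period for a canonical indel.

    * ``is_duplication``: the indel sequence equals the immediately
      adjacent upstream or downstream flank of equal length.
    * ``is_inversion_of_flank``: it equals the reversal of such a flank.
    * ``is_shift``: the sequence occurs within ``shift_window`` bp of
      either flank but not adjacently.

    A flag is None when the corresponding flank is truncated by the
    chromosome edge.
    """
    seq = indel.sequence
    n = len(seq)
    left_of, right_of = _flank_anchors(indel.canonical_pos, indel.op, n)
    first, last = genome.chromosome_span(indel.chromosome)

    def safe_fetch(lo: int, hi: int) -> Optional[str]:
        if lo < first or hi > last or lo > hi:
            return None
        return genome.fetch(indel.chromosome, lo, hi)

    left_adj = safe_fetch(left_of - n + 1, left_of)
    right_adj = safe_fetch(right_of, right_of + n - 1)

    report = GenesisReport(period_length=period_length(seq))
    adjacent = [f for f in (left_adj, right_adj) if f is not None]
    if adjacent:
        report.is_duplication = any(f == seq for f in adjacent)
        report.is_inversion_of_flank = any(f == seq[::-1] for f in adjacent)
    # shifted element: a non-adjacent copy within the scan window
    left_win = safe_fetch(max(first, left_of - shift_window + 1), left_of)
    right_win = safe_fetch(right_of, min(last, right_of + shift_window - 1))
    if left_win is None and right_win is None:
        report.is_shift = None
    else:
        hit = False
        if left_win and n <= len(left_win):
            # adjacent placement is the suffix of the left window
            hit = seq in left_win[:-1]
        if not hit and right_win and n <= len(right_win):
            # adjacent placement is the prefix of the right window
            hit = seq in right_win[1:]
        report.is_shift = hit
    report.transposon_flag = transposon_flag(
        indel.chromosome, indel.canonical_pos, indel.op, seq, genome)
    return report
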