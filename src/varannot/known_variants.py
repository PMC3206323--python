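"""Known / novel / alternative status against a local known-variants VCF.

SNP and MNP records are indexed by position and span; indel records are
stored under their canonical (left-aligned) placement, so redundant
database entries for one physical indel collapse onto one key and an input
indel matches a known record annotated at any equivalent placement.
"""

from __future__ import annotations

import logging
from typing import Optional

import pysam

from .gene_model import ReferenceBoundsError, chrom_pos
from .indel_analysis import CanonicalIndel, canonicalize
from .variant_io import VariantRecord, _normalize_vcf_allele_pair

logger = logging.getLogger("varannot")

KNOWN = "KNOWN"
NOVEL = "NOVEL"
ALTERNATIVE = "ALTERNATIVE"


class KnownVariantDB:
    """Position-indexed store of known variants; lookups never mutate it."""

    def __init__(self, genome=None) -> None:
        self._genome = genome  # needed to canonicalize query indels
        # (chrom, start, end) -> list of (id, ref, frozenset of alts)
        self._subst: dict[tuple[str, int, int], list] = {}
        # canonical indel -> list of ids
        self._indels: dict[CanonicalIndel, list[str]] = {}
        # (chrom, start) -> ids of any record anchored there (collision index)
        self._by_pos: dict[tuple[str, int], list[str]] = {}

    # -- construction --------------------------------------------------
    def add_substitution(self, rec_id: str, chromosome: str, start: int,
                         end: int, ref: str, alts: list[str]) -> None:
        entry = (rec_id, ref.upper(), frozenset(a.upper() for a in alts))
        self._subst.setdefault((chromosome, start, end), []).append(entry)
        self._by_pos.setdefault((chromosome, start), []).append(rec_id)

    def add_indel(self, rec_id: str, chromosome: str, pos: int, ref: str,
                  alt: str, genome) -> None:
        key = canonicalize(chromosome, pos, ref, alt, genome)
        ids = self._indels.setdefault(key, [])
        if rec_id not in ids:
            ids.append(rec_id)
        self._by_pos.setdefault((chromosome, key.canonical_pos), []).append(rec_id)
        if pos != key.canonical_pos:
            self._by_pos.setdefault((chromosome, pos), []).append(rec_id)

    def __len__(self) -> int:
        return len(self._subst) + len(self._indels)

    # -- lookup ---------------------------------------------------------
    def status_of(self, variant: VariantRecord,
                  ref_offset: int = 1) -> tuple[str, list[str]]:
        """(status, ids) for one verified input variant.

        KNOWN: coordinates and at least one alternative allele coincide
        with a known record (indels: canonical placements equal).
        ALTERNATIVE: a known record shares the coordinates but no allele.
        NOVEL: otherwise; ids is then empty.
        """
        start = chrom_pos(variant.rel_start, ref_offset)
        end = chrom_pos(variant.rel_end, ref_offset)
        chrom = variant.chromosome
        is_indel = variant.is_insertion or any(
            a == "" for a in variant.alt_alleles)
        if is_indel and self._genome is not None:
            return self._indel_status(variant, chrom, start)
        matches: list[str] = []
        colliders: list[str] = []
        for rec_id, ref, alts in self._subst.get((chrom, start, end), []):
            if variant.ref_allele is not None and \
                    variant.ref_allele.upper() != ref:
                colliders.append(rec_id)
            elif any(a.upper() in alts for a in variant.alt_alleles):
                matches.append(rec_id)
            else:
                colliders.append(rec_id)
        if matches:
            return KNOWN, matches
        colliders += [i for i in self._by_pos.get((chrom, start), [])
                      if i not in colliders]
        if colliders:
            return ALTERNATIVE, colliders
        return NOVEL, []

    def _indel_status(self, variant: VariantRecord, chrom: str,
                      start: int) -> tuple[str, list[str]]:
        alt = next((a for a in variant.alt_alleles
                    if a != (variant.ref_allele or "")), "")
        try:
            key = canonicalize(chrom, start, variant.ref_allele or "", alt,
                               self._genome)
        except (ValueError, ReferenceBoundsError):
            return NOVEL, []
        ids = self._indels.get(key)
        if ids:
            return KNOWN, list(ids)
        colliders = self._by_pos.get((chrom, key.canonical_pos), []) or \
            self._by_pos.get((chrom, start), [])
        if colliders:
            return ALTERNATIVE, list(dict.fromkeys(colliders))
        return NOVEL, []


def load_known(path: str, genome) -> KnownVariantDB:
    """Load a known-variants VCF into an indexed store.

    Indels are canonicalized before indexing; records whose REF disagrees
    with the genome are skipped with a warning.
    """
    db = KnownVariantDB(genome)
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            rec_id = rec.id or f"{rec.chrom}:{rec.pos}"
            subst_alts: dict[tuple[int, int, str], list[str]] = {}
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or "[" in alt or "]" in alt:
                    continue
                s, e, ref_a, alt_a = _normalize_vcf_allele_pair(
                    rec.pos, rec.ref, alt)
                if ref_a and genome.fetch(str(rec.chrom), s, e) != ref_a:
                    logger.warning("known-variants record %s: REF mismatch "
                                   "at %s:%d; skipped", rec_id, rec.chrom, s)
                    continue
                if ref_a == "" or alt_a == "":
                    db.add_indel(rec_id, str(rec.chrom), s, ref_a, alt_a, genome)
                else:
                    subst_alts.setdefault((s, e, ref_a), []).append(alt_a)
            for (s, e, ref_a), alts in subst_alts.items():
                db.add_substitution(rec_id, str(rec.chrom), s, e, ref_a, alts)
    return db
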