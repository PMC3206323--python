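"""Variant-list input and result output.

Input formats: the six-column variant table (Name, Chromosome, RelStart,
RelEnd, AltAlleles, RefAllele), VCF 4.x (via pysam) and pgSnp.  Output:
the basic per-variant table, the detailed per-(variant, transcript) table,
a plain-text summary report, HTML renderings of both tables, and a GFF3
export.

Allele conventions: coordinates are 1-based with inclusive ends; an empty
allele string encodes the em-dash gap of the table format (deletion: alt
"" with ref = deleted bases; insertion: ref "" with the inserted bases
placed between rel_start - 1 and rel_start and rel_end == rel_start).
Heterozygous calls may use "X/Y" or a single IUPAC ambiguity code; up to
three alternative alleles are kept (pooled-DNA calls).
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass, field
from typing import Optional

import pysam
from Bio.Data import IUPACData

logger = logging.getLogger("varannot")

NA = "NA"
GAP_CHARS = {"-", "—", "–", "."}  # '-', em dash, en dash


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One input variant in relative (reference-slice) coordinates."""

    name: str
    chromosome: str
    rel_start: int
    rel_end: int
    alt_alleles: list[str]
    ref_allele: Optional[str]  # None: unknown, fill from the reference

    def __post_init__(self) -> None:
        if self.rel_start > self.rel_end:
            raise ValueError(
                f"{self.name}: rel_start {self.rel_start} > rel_end {self.rel_end}")
        if not self.alt_alleles:
            raise ValueError(f"{self.name}: no alternative allele")
        if len(self.alt_alleles) > 3:
            raise ValueError(f"{self.name}: more than three alternative alleles")
        if self.ref_allele is not None and all(
                a.upper() == self.ref_allele.upper() for a in self.alt_alleles):
            raise ValueError(f"{self.name}: all alternative alleles equal the reference")

    @property
    def is_insertion(self) -> bool:
        return self.ref_allele == ""

    @property
    def is_deletion(self) -> bool:
        return self.ref_allele is not None and self.ref_allele != "" and \
            any(a == "" for a in self.alt_alleles)


@dataclass
class BasicRow:
    """One basic-table row; exactly one per input record."""

    name: str
    chromosome: str
    rel_start: int
    rel_end: int
    chrom_start: int
    chrom_end: int
    region: str = NA
    variant_type: str = NA
    func_class: str = "NONE"
    nearest_gene: str = NA
    distance: Optional[int] = None
    status: str = NA
    ids: list[str] = field(default_factory=list)
    insertion: bool = False


@dataclass
class DetailedRow:
    """One detailed-table row per (variant, transcript, class)."""

    name: str
    chromosome: str
    rel_start: int
    rel_end: int
    alt_alleles: list[str]
    ref_allele: Optional[str]
    codon: Optional[str] = None
    amino_acid: Optional[str] = None
    ref_amino_acid: Optional[str] = None
    func_class: str = NA
    transcript_id: str = NA
    strand: Optional[int] = None
    ids: list[str] = field(default_factory=list)
    cons_score: Optional[float] = None
    protein_domain: Optional[str] = None


# ---------------------------------------------------------------------------
# allele parsing helpers
# ---------------------------------------------------------------------------

def _expand_allele_field(text: str) -> list[str]:
    """Expand an AltAlleles cell into a list of allele strings.

    "X/Y" (or X/Y/Z) splits on the slash; a single IUPAC ambiguity symbol
    expands to its bases; a gap character maps to the empty allele.
    """
    text = text.strip()
    if "/" in text:
        return [_one_allele(part) for part in text.split("/")]
    return _expand_iupac_single(text)


def _one_allele(text: str) -> str:
    text = text.strip().upper()
    if text in GAP_CHARS or text == "":
        return ""
    return text


def _expand_iupac_single(text: str) -> list[str]:
    allele = _one_allele(text)
    if len(allele) == 1 and allele not in "ACGTN":
        bases = IUPACData.ambiguous_dna_values.get(allele)
        if bases and 1 < len(bases) <= 3:
            return list(bases)
    return [allele]


class VariantParseError(ValueError):
    """A record-level parse problem; carries the offending line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_variant_table(text: str, has_header: Optional[bool] = None
                        ) -> tuple[list[VariantRecord], list[VariantParseError]]:
    """Parse the six-column variant table.

    ``has_header`` None auto-detects a header line by testing whether the
    third column of the first line is numeric.  Malformed lines are
    reported as :class:`VariantParseError` entries and skipped; parsing
    continues.  Returns (records, errors) with input order preserved.
    """
    records: list[VariantRecord] = []
    errors: list[VariantParseError] = []
    content = [(lineno, line) for lineno, line in enumerate(text.splitlines(), 1)
               if line.strip() and not line.lstrip().startswith("#")]
    if not content:
        return records, errors
    first_fields = content[0][1].split()
    if has_header is None:
        has_header = len(first_fields) >= 3 and not _is_int(first_fields[2])
    if has_header:
        content = content[1:]
    for lineno, line in content:
        fields = line.split()
        if len(fields) != 6:
            errors.append(VariantParseError(
                lineno, f"expected 6 columns, found {len(fields)}"))
            continue
        name, chrom, s, e, alt_text, ref_text = fields
        try:
            rel_start, rel_end = int(s), int(e)
        except ValueError:
            errors.append(VariantParseError(lineno, "non-numeric coordinates"))
            continue
        try:
            record = VariantRecord(
                name=name, chromosome=chrom, rel_start=rel_start,
                rel_end=rel_end, alt_alleles=_expand_allele_field(alt_text),
                ref_allele=_one_allele(ref_text))
        except ValueError as exc:
            errors.append(VariantParseError(lineno, str(exc)))
            continue
        records.append(record)
    for err in errors:
        logger.warning("variant table: %s", err)
    return records, errors


def _is_int(text: str) -> bool:
    try:
        int(text)
        return True
    except ValueError:
        return False


def _normalize_vcf_allele_pair(pos: int, ref: str, alt: str
                               ) -> tuple[int, int, str, str]:
    """VCF (POS, REF, ALT) -> (rel_start, rel_end, ref_allele, alt_allele).

    Shared leading bases are stripped so indels follow the gap convention;
    equal-length pairs (SNP/MNP) are kept as printed.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == len(alt):
        return pos, pos + len(ref) - 1, ref, alt
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if ref == "":   # insertion between pos-1 and pos
        return pos, pos, "", alt
    if alt == "":   # deletion of ref starting at pos
        return pos, pos + len(ref) - 1, ref, ""
    # complex substitution left after trimming: keep as block substitution
    return pos, pos + len(ref) - 1, ref, alt


def parse_vcf(path: str) -> tuple[list[VariantRecord], list[VariantParseError]]:
    """Read a VCF 4.x file into VariantRecords.

    Multi-allelic sites are split per ALT, then ALTs that normalize to the
    same (span, ref) are pooled into one record's alt list; ALTs landing on
    different spans (mixed SNP + indel sites) become separate records.
    Symbolic and breakend ALTs are skipped with a warning.
    """
    records: list[VariantRecord] = []
    errors: list[VariantParseError] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            name = rec.id or f"{rec.chrom}:{rec.pos}"
            groups: dict[tuple[int, int, str], list[str]] = {}
            for alt in rec.alts or ():
                if alt is None or alt.startswith("<") or "[" in alt or "]" in alt:
                    logger.warning("VCF %s: symbolic ALT %r skipped", name, alt)
                    continue
                s, e, ref_a, alt_a = _normalize_vcf_allele_pair(
                    rec.pos, rec.ref, alt)
                groups.setdefault((s, e, ref_a), []).append(alt_a)
            for i, ((s, e, ref_a), alts) in enumerate(sorted(groups.items())):
                rec_name = name if len(groups) == 1 else f"{name}_{i + 1}"
                try:
                    records.append(VariantRecord(
                        name=rec_name, chromosome=str(rec.chrom), rel_start=s,
                        rel_end=e, alt_alleles=alts[:3], ref_allele=ref_a))
                except ValueError as exc:
                    errors.append(VariantParseError(0, f"{rec_name}: {exc}"))
    return records, errors


def parse_pgsnp(path: str, genome=None, ref_offset: int = 1
                ) -> tuple[list[VariantRecord], list[VariantParseError]]:
    """Read a pgSnp (Personal Genome SNP) track.

    pgSnp is BED-based (0-based half-open) and carries observed alleles but
    no reference allele; when ``genome`` is given the reference allele is
    filled from it, otherwise it is left None for the pipeline to resolve.
    Observed alleles matching the reference are dropped from the alt list.
    """
    records: list[VariantRecord] = []
    errors: list[VariantParseError] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                errors.append(VariantParseError(lineno, "fewer than 4 columns"))
                continue
            chrom, start0, end0, allele_text = fields[0], fields[1], fields[2], fields[3]
            try:
                rel_start, rel_end = int(start0) + 1, int(end0)
            except ValueError:
                errors.append(VariantParseError(lineno, "non-numeric coordinates"))
                continue
            if rel_end < rel_start:   # zero-length span: insertion point
                rel_end = rel_start
            alts = [_one_allele(a) for a in allele_text.split("/")]
            ref: Optional[str] = None
            if genome is not None:
                from .gene_model import chrom_pos
                ref = genome.fetch(chrom, chrom_pos(rel_start, ref_offset),
                                   chrom_pos(rel_end, ref_offset))
                non_ref = [a for a in alts if a != ref]
                alts = non_ref or alts
            try:
                records.append(VariantRecord(
                    name=f"{chrom}:{rel_start}", chromosome=chrom,
                    rel_start=rel_start, rel_end=rel_end,
                    alt_alleles=alts[:3], ref_allele=ref))
            except ValueError as exc:
                errors.append(VariantParseError(lineno, str(exc)))
    for err in errors:
        logger.warning("pgSnp: %s", err)
    return records, errors


# ---------------------------------------------------------------------------
# formatting helpers
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, float) and value != value:  # NaN
        return NA
    return str(value)


def _fmt_allele(allele: Optional[str]) -> str:
    if allele is None:
        return NA
    return allele if allele != "" else "-"


def _fmt_ids(ids: list[str]) -> str:
    return ", ".join(ids) if ids else NA


BASIC_COLUMNS = ["Name", "Chr", "Start", "End", "ChromStart", "ChromEnd",
                 "Region", "Type", "FuncClass", "NearestGene", "Distance",
                 "Status", "ID"]

DETAILED_COLUMNS = ["Name", "Chr", "Start", "End", "AltAllele1", "AltAllele2",
                    "AltAllele3", "RefAllele", "Codon", "AminoAcid",
                    "RefAminoAcid", "FuncClass", "Transcript", "Strand", "ID",
                    "ConsScore", "ProteinDomain"]


def _basic_cells(row: BasicRow) -> list[str]:
    return [row.name, row.chromosome, str(row.rel_start), str(row.rel_end),
            str(row.chrom_start), str(row.chrom_end), row.region,
            row.variant_type, row.func_class, _fmt(row.nearest_gene),
            _fmt(row.distance), row.status, _fmt_ids(row.ids)]


def _detailed_cells(row: DetailedRow) -> list[str]:
    alts = (list(row.alt_alleles) + [None, None, None])[:3]
    return [row.name, row.chromosome, str(row.rel_start), str(row.rel_end),
            _fmt_allele(alts[0]), _fmt_allele(alts[1]), _fmt_allele(alts[2]),
            _fmt_allele(row.ref_allele), _fmt(row.codon), _fmt(row.amino_acid),
            _fmt(row.ref_amino_acid), row.func_class, row.transcript_id,
            _fmt(row.strand), _fmt_ids(row.ids), _fmt(row.cons_score),
            _fmt(row.protein_domain)]


def _write_table(path: str, columns: list[str], rows: list[list[str]],
                 fmt: str, id_column: Optional[int] = None,
                 url_template: Optional[str] = None) -> None:
    if fmt == "text":
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for cells in rows:
                fh.write("\t".join(cells) + "\n")
        return
    if fmt != "html":
        raise ValueError(f"unknown output format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
                 "<title>varannot</title></head><body>\n<table border='1'>\n")
        fh.write("<tr>" + "".join(f"<th>{html.escape(c)}</th>" for c in columns)
                 + "</tr>\n")
        for cells in rows:
            parts = []
            for i, cell in enumerate(cells):
                if (id_column is not None and i == id_column
                        and url_template and cell != NA):
                    links = []
                    for one in cell.split(", "):
                        url = html.escape(url_template.format(id=one), quote=True)
                        links.append(f"<a href='{url}'>{html.escape(one)}</a>")
                    parts.append("<td>" + ", ".join(links) + "</td>")
                else:
                    parts.append(f"<td>{html.escape(cell)}</td>")
            fh.write("<tr>" + "".join(parts) + "</tr>\n")
        fh.write("</table>\n</body></html>\n")


def write_basic(rows: list[BasicRow], path: str, fmt: str = "text",
                url_template: Optional[str] = None) -> None:
    """Write the basic table ("text" TSV or "html")."""
    _write_table(path, BASIC_COLUMNS, [_basic_cells(r) for r in rows], fmt,
                 id_column=BASIC_COLUMNS.index("ID"), url_template=url_template)


def write_detailed(rows: list[DetailedRow], path: str, fmt: str = "text",
                   url_template: Optional[str] = None) -> None:
    """Write the detailed table ("text" TSV or "html")."""
    _write_table(path, DETAILED_COLUMNS, [_detailed_cells(r) for r in rows],
                 fmt, id_column=DETAILED_COLUMNS.index("ID"),
                 url_template=url_template)


def summarize(rows: list[BasicRow],
              detailed: Optional[list[DetailedRow]] = None) -> dict:
    """Key figures of a run, as a plain dict (also used by write_report)."""
    by_class: dict[str, int] = {}
    by_type: dict[str, int] = {}
    by_status: dict[str, int] = {}
    mismatches = 0
    for row in rows:
        by_type[row.variant_type] = by_type.get(row.variant_type, 0) + 1
        by_status[row.status] = by_status.get(row.status, 0) + 1
        if row.status == "REF_MISMATCH":
            mismatches += 1
    class_rows = detailed if detailed is not None else []
    seen: set[tuple[str, str]] = set()
    for d in class_rows:
        if d.func_class != NA and (d.name, d.func_class) not in seen:
            seen.add((d.name, d.func_class))
            by_class[d.func_class] = by_class.get(d.func_class, 0) + 1
    return {
        "variations_processed": len(rows),
        "reference_mismatches": mismatches,
        "by_functional_class": dict(sorted(by_class.items())),
        "by_type": dict(sorted(by_type.items())),
        "by_status": dict(sorted(by_status.items())),
    }


def write_report(rows: list[BasicRow], path: str,
                 detailed: Optional[list[DetailedRow]] = None,
                 provenance: Optional[dict] = None) -> None:
    """Write the plain-text summary report."""
    summary = summarize(rows, detailed)
    with open(path, "w") as fh:
        fh.write("varannot run report\n===================\n\n")
        if provenance:
            fh.write("configuration:\n")
            for key, value in provenance.items():
                fh.write(f"  {key}: {value}\n")
            fh.write("\n")
        fh.write(f"variations processed: {summary['variations_processed']}\n")
        fh.write("reference mismatches: "
                 f"{summary['reference_mismatches']}\n\n")
        for title, key in [("functional class", "by_functional_class"),
                           ("variant type", "by_type"),
                           ("status", "by_status")]:
            fh.write(f"variations per {title}:\n")
            counts = summary[key]
            if not counts:
                fh.write("  (none)\n")
            for label, count in counts.items():
                fh.write(f"  {label}: {count}\n")
            fh.write("\n")


def _gff_escape(text: str) -> str:
    out = []
    for ch in text:
        out.append(f"%{ord(ch):02X}" if ch in "=;,&\t%" else ch)
    return "".join(out)


def export_gff(rows: list[BasicRow], path: str,
               detailed: Optional[list[DetailedRow]] = None) -> None:
    """Export annotated variants as GFF3 features.

    Coordinates are chromosomal and 1-based.  An insertion (zero-length
    reference) is emitted as a length-1 feature anchored at the insertion
    point with an ``insertion=true`` attribute, since GFF3 cannot encode a
    zero-length span.  Functional classes and status go into column 9.
    """
    classes_by_name: dict[str, list[str]] = {}
    for d in detailed or []:
        if d.func_class != NA:
            classes_by_name.setdefault(d.name, [])
            if d.func_class not in classes_by_name[d.name]:
                classes_by_name[d.name].append(d.func_class)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            start, end = row.chrom_start, row.chrom_end
            attrs = [f"ID={_gff_escape(row.name)}"]
            if row.insertion:  # zero-length span anchored at the insertion point
                start, end = row.chrom_start, row.chrom_start
                attrs.append("insertion=true")
            func = classes_by_name.get(row.name) or (
                [row.func_class] if row.func_class != "NONE" else [])
            if func:
                attrs.append("func_class=" + ",".join(_gff_escape(c) for c in func))
            attrs.append(f"status={_gff_escape(row.status)}")
            if row.ids:
                attrs.append("known_ids=" + ",".join(_gff_escape(i) for i in row.ids))
            fh.write("\t".join([
                row.chromosome, "varannot", "sequence_variant", str(start),
                str(end), ".", ".", ".", ";".join(attrs)]) + "\n")
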