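"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: edits
are applied to raw strings, nearest genes are found by exhaustive scan,
and translations go through Bio.Seq.  Tests compare the implementation
against these.
"""

from __future__ import annotations

import random

import pytest
from Bio.Seq import Seq

from varannot import fixtures as fx
from varannot.gene_model import InMemoryGenome


@pytest.fixture(scope="session")
def default_bundle():
    return fx.make_fixture()


@pytest.fixture(scope="session")
def worked_bundle():
    return fx.worked_example()


@pytest.fixture()
def fixture_files(tmp_path):
    return fx.make_fixture(outdir=tmp_path / "fixture")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def apply_edit(sequence: str, first_pos: int, pos: int, ref: str,
               alt: str) -> str:
    """Apply one edit to a raw sequence string (1-based coordinates).

    ``first_pos`` is the coordinate of sequence[0].  A deletion removes
    ``ref`` starting at ``pos``; an insertion (empty ref) inserts ``alt``
    before ``pos``; a substitution replaces in place.
    """
    i = pos - first_pos
    assert 0 <= i <= len(sequence)
    if ref:
        assert sequence[i:i + len(ref)] == ref, "oracle: ref mismatch"
    return sequence[:i] + alt + sequence[i + len(ref):]


def naive_nearest_gene(genes, start, end):
    """Exhaustive-scan nearest gene with the documented tie-break.

    ``genes`` is a list of (gene_id, gstart, gend).  Returns
    (gene_id, signed_distance) or (None, inf).
    """
    best = None
    for gene_id, gs, ge in genes:
        if not (end < gs or start > ge):
            key = (0, gs, gene_id)
            cand = (key, gene_id, 0)
        elif ge < start:
            key = (start - ge, gs, gene_id)
            cand = (key, gene_id, -(start - ge))
        else:
            key = (gs - end, gs, gene_id)
            cand = (key, gene_id, gs - end)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        return None, float("inf")
    return best[1], best[2]


def translate_cds(cds: str, table_id: int = 1) -> str:
    """Independent translation of a CDS (stops as '*')."""
    usable = len(cds) // 3 * 3
    return str(Seq(cds[:usable]).translate(table=table_id))


def repeat_rich_genome(seed: int, chrom: str = "rep") -> InMemoryGenome:
    """A genome dominated by homopolymer, di- and trinucleotide tracts."""
    rng = random.Random(seed)
    parts = []
    for _ in range(40):
        unit = rng.choice(["A", "T", "GA", "CT", "GAT", "CTG", "GAGGCT"])
        copies = rng.randint(4, 20)
        spacer = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 10)))
        parts.append(spacer + unit * copies)
    parts.append("".join(rng.choice("ACGT") for _ in range(20)))
    return InMemoryGenome({chrom: "".join(parts)})


def random_indels_in(genome: InMemoryGenome, chrom: str, n: int, seed: int):
    """Random pure indels, biased into the repeat tracts.

    Returns a list of (name, chrom, pos, ref, alt) tuples valid against
    the genome (deletion refs are real genome slices).
    """
    rng = random.Random(seed)
    first, last = genome.chromosome_span(chrom)
    out = []
    for i in range(n):
        length = rng.randint(1, 6)
        if rng.random() < 0.6:  # deletion
            pos = rng.randint(first + 1, last - length)
            ref = genome.fetch(chrom, pos, pos + length - 1)
            out.append((f"del{i}", chrom, pos, ref, ""))
        else:  # insertion: often a copy of adjacent sequence
            pos = rng.randint(first + length + 1, last - 1)
            if rng.random() < 0.7:
                ins = genome.fetch(chrom, pos - length, pos - 1)
            else:
                ins = "".join(rng.choice("ACGT") for _ in range(length))
            out.append((f"ins{i}", chrom, pos, "", ins))
    return out
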