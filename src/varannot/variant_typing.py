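"""Variant-type classification: SNP, MNP, inversion or indel.

The type is a pure function of the (reference, alternative) allele pair:

* different lengths            -> INDEL
* both length 1                -> SNP
* alt == reversed(ref), len>1  -> INVERSION
* otherwise                    -> MNP

"Inversion" here means plain character reversal of the reference allele,
not reverse complement; reverse-complement semantics are available via the
``inversion_semantics`` switch for users who prefer the biological reading.
With several alternative alleles the most complex per-allele type is
reported (INDEL > INVERSION > MNP > SNP), since the basic output table has
a single Type cell.
"""

from __future__ import annotations

from enum import Enum

from .gene_model import revcomp


class VariantType(str, Enum):
    SNP = "SNP"
    MNP = "MNP"
    INVERSION = "INVERSION"
    INDEL = "INDEL"


# most complex last
_COMPLEXITY = [VariantType.SNP, VariantType.MNP,
               VariantType.INVERSION, VariantType.INDEL]


def classify_type(ref_allele: str, alt_allele: str,
                  inversion_semantics: str = "reversal") -> VariantType:
    """Type of a single (ref, alt) allele pair.

    ``inversion_semantics`` is ``"reversal"`` (default) or ``"revcomp"``.
    Raises ValueError when the alleles are identical.
    """
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if ref == alt:
        raise ValueError(f"reference and alternative allele identical: {ref!r}")
    if len(ref) != len(alt):
        return VariantType.INDEL
    if len(ref) == 1:
        return VariantType.SNP
    inverted = ref[::-1] if inversion_semantics == "reversal" else revcomp(ref)
    if alt == inverted:
        return VariantType.INVERSION
    return VariantType.MNP


def classify_variant_type(ref_allele: str, alt_alleles: list[str],
                          inversion_semantics: str = "reversal") -> VariantType:
    """Most complex type over all alternative alleles of one record."""
    types = [classify_type(ref_allele, alt, inversion_semantics)
             for alt in alt_alleles if alt.upper() != ref_allele.upper()]
    if not types:
        raise ValueError("no alternative allele differs from the reference")
    return max(types, key=_COMPLEXITY.index)
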