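# varannot

Offline functional annotation of sequence variants against transcript
models.

Resequencing projects produce long lists of called variants; the question
that matters downstream is what each one *does*: does it change an amino
acid, truncate a protein, disturb a splice site, sit in a promoter-scale
flanking region — and is it already catalogued or new?  `varannot`
answers this for SNPs, multi-nucleotide polymorphisms (MNPs), inversions
and indels, entirely offline, from three local files: a variant list, a
gene annotation (GFF3 or BED12) and a reference FASTA.

## What it computes

For every variant, against every transcript of every overlapping gene:

* **Variant type** from the allele pair: SNP (both length 1), indel
  (lengths differ), inversion (alt = character reversal of ref, length
  > 1), otherwise MNP.
* **One or more of 21 functional classes**: `INTERGENIC`, `UPSTREAM`,
  `DOWNSTREAM` (flanking within 5 kb, strand-aware),
  `WITHIN_NON_CODING_TRANSCRIPT`, `INTRONIC`, `5PRIME_UTR`, `3PRIME_UTR`,
  `SYNONYMOUS_CODING`, `NON_SYNONYMOUS_CODING`, `FRAMEKEEP`, `FRAMESHIFT`,
  `STOP_GAINED`, `STOP_LOST`, `POTENTIAL_START_GAINED`, `START_LOST`,
  `DELETE_EXONS`, `MERGE_EXONS`, `ACCEPTOR`, `DONOR`, `SPLICE_SITE`,
  `ESSENTIAL_SPLICE_SITE`.  15 classes apply to SNPs, 19 to indels.
* **Codon consequences** under a selectable genetic code (standard,
  prokaryotes, yeasts, mycoplasma, mitochondria): the affected codon with
  an IUPAC symbol at the variable position (e.g. `GCS` for a G/C
  heterozygote third base), reference and alternative amino acids.
* **Known / novel / alternative status** against a local known-variants
  VCF.  Indels are left-aligned to a canonical placement first, so a
  deletion annotated anywhere inside a repeat run matches a database
  record annotated at any other placement of the same run.
* **Indel characterization**: canonical placement, equivalence groups of
  redundantly annotated indels, repeat period length, evolutionary-genesis
  flags (duplication of an adjacent flank, reversal of a flank, shifted
  element) and a 13 bp flanking-sequence transposon check.

Outputs: a basic per-variant table, a detailed per-(variant, transcript,
class) table (text and HTML), a plain-text report with key counts, and a
GFF3 export for genome browsers.

## Worked example

The test fixtures include a seven-variant list in the six-column input
format (`Name Chromosome RelStart RelEnd AltAlleles RefAllele`; `—` is the
gap allele, `X/Y` a heterozygote) together with a matching synthetic
genome and annotation:

```python
from varannot import annotate_variants
from varannot import fixtures

bundle = fixtures.worked_example()
basic, detailed = annotate_variants(bundle.records, bundle.gene_index,
                                    bundle.genome, known_db=bundle.known_db)
for r in basic:
    print(r.name, r.region, r.variant_type, r.func_class, r.status)
```

prints

```
var1 CODING_REGION SNP SYNONYMOUS_CODING KNOWN
var2 CODING_REGION SNP NON_SYNONYMOUS_CODING NOVEL
var3 DOWNSTREAM INDEL NONE KNOWN
var4 INTRONIC INVERSION NONE NOVEL
var5 INTRONIC SNP NONE NOVEL
var6 CODING_REGION SNP NON_SYNONYMOUS_CODING KNOWN
var7 CODING_REGION INDEL FRAMESHIFT NOVEL
```

`var1` is a G→C substitution at the third position of an alanine codon of
a minus-strand gene: the detailed table shows codon `GCS` (S = C or G),
Ala→Ala, in both transcripts of the gene.  `var2` hits the first position
of a lysine codon (`MAA`, Lys→Gln).  `var3` is an insertion 316 bp
downstream of a neighbouring gene and carries two database identifiers —
two records that are one and the same indel once canonicalized.  `var7`
is a 2 bp coding deletion, hence `FRAMESHIFT`.

From the shell, against files:

```bash
python -m varannot.cli --help   # or the `varannot` console script
varannot --variants variants.tsv --gff genes.gff3 --fasta genome.fa \
         --known known.vcf --out results/run
```

## Indel equivalence

Databases often carry several records for one physical indel: deleting
any single `A` from a 20 bp poly-A run yields the same sequence.
`varannot.canonicalize` left-aligns an indel to the smallest equivalent
position and `group_equivalent` partitions a record list by that key:

```python
from varannot import InMemoryGenome, group_equivalent
genome = InMemoryGenome({"12": "TCTC" + "A" * 20 + "GAAC"})
records = [("a", "12", 7, "A", ""), ("b", "12", 15, "A", "")]
print(group_equivalent(records, genome)[0].members)   # ['a', 'b']
```

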