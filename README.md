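# varannot

Offline functional annotation of DNA sequence variants, with per-sample
detection of loci consistent with recessive or compound-heterozygous
inheritance.

Resequencing experiments yield thousands to millions of variant sites, most
of which must be triaged before any functional follow-up: which variants
change a protein, which fall in splice sites, which were already catalogued,
and which sit at evolutionarily conserved bases. `varannot` performs that
triage locally, with no network access, against three user-supplied
resources:

- a **gene-model table** (genePred dialect: transcript and CDS bounds,
  comma-separated exon lists, per-exon frames; 0-based half-open),
- a **known-variant catalog** (dbSNP-dialect TSV: identifier, position,
  strand, alleles as recorded on that strand, heterozygosity),
- a **conservation track** (wiggle `fixedStep`/`variableStep`, phastCons
  scores in [0, 1]).

## What it computes

Each variant (SNP or indel) is placed into a functional category relative to
every overlapping transcript: exonic replacement (nonsynonymous) or silent
(synonymous) SNP, exonic indel, splice donor/acceptor (the two intronic
bases flanking each exon boundary, the canonical GT/AG dinucleotide
positions), 5'/3' UTR, intronic, or intergenic. For coding SNPs the spliced
CDS is assembled exon by exon (reverse-complemented for `-`-strand models)
and the consequence is reported as the amino-acid triple
(ref AA, codon index `⌊offset/3⌋+1`, alt AA) under the standard genetic
code. When several transcripts overlap, the single reported category is the
most severe under a fixed total order and all overlapping accessions are
retained. The output is an 18-column record per site: chromosome, 1-based
position, gene name and strand, category, alleles, variation type, the
amino-acid triple, gene-model warnings, transcript accessions, catalog
id/heterozygosity/orientation (alleles complemented for `-`-strand records
at match time but reported as stored), conservation score, and sample ids.

Heterozygosity is encoded in the allele column: a two-base IUPAC ambiguity
code covering the reference (e.g. `W` at ref `A` ⇒ het A/T) means
heterozygous, a plain non-reference base homozygous.

A locus is flagged as a recessive/compound-het candidate in a sample when
three criteria all hold: (1) ≥1 homozygous or ≥2 heterozygous replacement
variants in the same gene, (2) no supporting position present in the
known-variant catalog, and (3) every supporting position's conservation
score strictly above a user-chosen threshold.

## Worked example

Generate a self-contained synthetic dataset (10 kb chromosome, four
multi-exon genes on both strands, planted variants with known truth), then
annotate the three-sample cohort:

```sh
varannot fixtures --seed 1 --out demo
varannot annotate \
    --reference demo/reference.fa --genes demo/genes.tsv \
    --snps demo/known_variants.tsv --conservation demo/conservation.wig \
    --input demo/cohort_variants.tsv --format list_with_samples \
    --phastcons-threshold 0.5 --out demo_out
```

which prints `annotated 10 sites -> demo_out` and writes four files.
`annotations.tsv` (first columns shown):

```
Chromosome  Genome Position  Gene Name  Gene Strand  Functional Category     ...  Ref AA  AA Pos  Alt AA
chrT        647              GENE1      +            Exonic Replacement SNP  ...  S       46      R
chrT        641              GENE1      +            Exonic Replacement SNP  ...  D       44      E
chrT        1307             GENE2      -            Exonic Replacement SNP  ...  W       58      L
```

The first row reads: the heterozygous call (`W` = A/T) at chrT:647 falls in
codon 46 of GENE1 and replaces serine with arginine. `recessive_summary.tsv`
contains exactly the two planted positives — a compound heterozygote
(two novel, conserved het replacements in GENE1 carried by sample S1) and a
homozygous candidate in GENE2:

```
sample_id  gene_name  mode          n_supporting  variant_positions
S1         GENE1      COMPOUND_HET  2             647;641
S1         GENE2      HOMOZYGOUS    1             1307
```

`annotations.bed` is a 0-based half-open track loadable in a genome
browser (`chrT  646  647  GENE1|Exonic Replacement SNP|T>W`), and `run.log`
records inputs parsed, rows deduplicated and per-category counts.

Variants can also come from aligned sequence fragments
(`--format fragments`, deriving SNPs and deletions by comparison against
the reference), a plain list without samples (`list`), or a single call
given on the command line (`single`). `varannot build-db` preprocesses the
resource tables into a reusable cache.

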