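# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open, the native convention of
genePred and BED. The two 1-based dialects are converted exactly once at a
boundary: wiggle declarations (1-based per the format standard) at parse
time, and list-of-variants / single-variant positions (1-based, the
genome-browser display convention users copy positions from) at parse time.
The reported `Genome Position` output field is 1-based again so it can be
pasted into a browser position box; the BED writer emits 0-based half-open
intervals. Known-variant table positions are stored 0-based.

## Gene models and validation

A transcript is held as accession, gene symbol, chromosome, strand,
transcript and CDS bounds, ordered non-overlapping exons and per-exon
frames. Frames follow the genePred rule: the number of coding bases in
transcript-earlier exons mod 3, with −1 for exons containing no coding
base. Models are validated against the reference at load time; the checks
are spliced-CDS length divisible by 3, ATG initiator, terminal stop, no
internal stop, stored frames equal to recomputed frames, and coordinates
within the chromosome. Warning codes propagate into output field 12 for
every variant annotated against the affected transcript, mirroring how
public gene tracks carry occasional malformed entries that downstream users
need to see rather than have silently repaired.

Transcript lookup uses a per-chromosome interval tree; its contract is
equivalence with a linear scan (enforced by a randomized property test),
not any particular storage format. The serialized cache written by
`build-db` is a convenience; correctness is defined over the in-memory
indexes.

## Functional classification

Per overlapping transcript, a site is: coding if inside the CDS portion of
an exon (SNPs are split into replacement/silent by translating the affected
codon; indels are one exonic-indel class — frameshift consequence
prediction is out of scope); UTR if exonic outside the CDS, with 5'/3'
assigned strand-aware; splice donor/acceptor if within the two intronic
bases adjacent to an exon boundary in transcription sense (the canonical
GT/AG dinucleotides — the minimal window, chosen because only these two
positions are near-invariant); otherwise intronic; intergenic when no
transcript bounds contain the site. Indels are classified by their first
affected reference base.

When transcripts disagree, one category must be reported. The collapse uses
a fixed total order (replacement > exonic indel > donor > acceptor >
silent > UTR > intronic > intergenic), ties broken by lowest accession for
determinism, and all overlapping accessions are kept in field 13. Severity
collapse is the only single-row rule that is deterministic and
order-independent; it is applied across all transcripts genome-wide, not
per gene.

Coding consequences assemble the spliced CDS from the exon/CDS
intersections in genomic order, reverse-complementing for `-`-strand
models. The codon index is `offset // 3 + 1`. Heterozygous IUPAC alleles
are resolved to their non-reference base before translation (standard code;
stop renders as `*`; a stop-creating or stop-destroying substitution is
still a replacement — no separate nonsense class). If a malformed model's
CDS length is not a multiple of 3 and the variant falls in the trailing
partial codon, the amino-acid fields stay empty and the model warning
carries the explanation; the site is reported at the more severe coding
class rather than guessed silent.

## Known-variant and conservation lookups

Catalog matching is by exact position. Record alleles are complemented onto
the reference strand when the record is stored on `-` before comparison,
but output fields 14–16 report the record exactly as stored (id,
heterozygosity, orientation) because orientation is itself an output field.
A position hit whose allele set does not cover the query is reported with
an `|allele_mismatch` flag on the id rather than suppressed: position-level
presence is what novelty filtering needs, while the flag preserves the
distinction for anyone who cares about allele identity.

Conservation scores are a sparse per-base map; positions never declared in
the source wiggle return a missing sentinel (`None`), never 0 — a missing
measurement and a measured 0 are different facts. Wiggle `span` assigns a
value to that many consecutive bases; scores outside [0, 1] are parse
errors.

## Variant input

Fragment-versus-reference calling compares an aligned fragment to its BED
interval base by base: mismatches are SNPs (ambiguity codes covering the
reference are heterozygous), `-` marks a deleted reference base, and runs
of adjacent gaps merge into one multi-base deletion; adjacent substitutions
remain separate SNP calls. Gaps are permitted only in the fragment, so this
dialect cannot express insertions; insertions enter through the list
formats with ref `-`, anchored at the base before the insertion. Identical
calls from overlapping fragments, and duplicate (sample, chromosome,
position) list rows, are deduplicated with a log entry each. The
fragment-relative position column of the list formats is parsed but unused;
no output field corresponds to it.

Zygosity is inferred from the allele encoding (two-base IUPAC code covering
the reference ⇒ het; plain non-reference base ⇒ hom; anything else,
including indels, unknown). The input formats carry no explicit genotype
column, and the two-base-code convention is the one encoding consistent
with single-column allele reporting.

## Recessive / compound-heterozygote detection

Candidates are replacement SNPs with known zygosity. Per sample and gene
(gene symbol, not transcript accession, so alleles on different transcripts
of one gene still pair): ≥1 homozygous candidate calls the homozygous mode,
≥2 heterozygous candidates the compound-het mode; a gene may yield both.
Each supporting variant must additionally be absent from the known-variant
catalog (any position-level hit vetoes, allele-matched or not) and have a
conservation score strictly above the configured threshold — "above" is
strict, and a missing score fails, since absent evidence should not pass a
conservation filter. The default threshold of 0.0 filters nothing beyond
requiring a present, positive score, as the threshold is intentionally a
user decision. No phasing is attempted: nothing in these inputs can
establish that two heterozygous alleles lie in trans, so compound-het calls
are candidates, not proofs.

## Synthetic data generator

The generator emulates the structural content of a small resequencing
study: one toy chromosome (default 10 kb — small enough that exhaustive
per-base oracles run in seconds), four multi-exon genes alternating
strands, each with a structurally valid CDS (random non-stop codons between
ATG and a stop, split across 2–4 exons with whole UTRs inside the terminal
exons), a known-variant catalog covering a deterministic subset of planted
variants (random record strands, alleles complemented onto the record
strand, plus one deliberate allele-mismatched position hit and background
records), a conservation track mixing `fixedStep` and `variableStep`
sections with controlled scores at variant positions (intergenic plants are
left uncovered to exercise the missing-score path), and a three-sample
cohort containing one compound-het positive, one homozygous positive and
four near-miss negatives that each fail exactly one criterion.

Every planted variant's expected annotation (category, amino-acid triple,
catalog match, score, recessive membership) is computed during generation
from the designed gene structure, not by running the annotator, so the
truth table is an independent target. Two structural guarantees exist
purely so that model corruptions are surgical: the 3' UTR begins with an
in-frame TAA (extending the CDS by one codon yields exactly an
internal-stop signature) and the second codon is never ATG (removing the
first codon yields exactly a missing-start signature).

What the generator does not emulate: realistic mutation rates, linkage,
allele-frequency spectra, overlapping genes, alternative transcripts of one
locus, sequencing error, or insertions in the fragment dialect. Passing
tests therefore demonstrate correctness of coordinate arithmetic,
classification logic and filtering semantics — not calibration on real
population data.

## Numerical and tie-break choices

- Category collapse ties break by lowest transcript accession; index query
  results are sorted, so classification is invariant to input order.
- Floats (heterozygosity, conservation) serialize via `repr`, making the
  TSV write→read round trip exact.
- All randomness in the generator flows from one `random.Random(seed)`;
  identical seeds give byte-identical bundles, and the pipeline itself is
  deterministic end to end.
- Problem sizes used by the test suite and the acceptance script — 10 kb
  chromosome, four genes, 1,000 random coding SNPs, five seeds for
  end-to-end recovery — keep exhaustive oracle comparison cheap while
  covering both strands, every category and every criterion.

## Known limitations

- No frameshift or protein-impact prediction; indels get positional
  classes only.
- No VCF ingestion (the list dialects predate it; adding a VCF reader is
  mechanical).
- Splice windows are fixed at 2 bp; extended splice regions are not
  modelled.
- Non-coding transcripts are classified with UTR sides degenerate at the
  empty CDS point.
- The known-variant dialect is this package's own 6-column definition;
  real dbSNP dumps need a one-off projection to it.
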