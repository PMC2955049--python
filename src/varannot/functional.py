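"""Functional classification of variant sites and amino-acid consequences.

Per overlapping transcript a variant is placed into one of twelve
categories (coding replacement/silent/indel, splice donor/acceptor,
5'/3' UTR, intronic, intergenic).  When several transcripts overlap, the
single reported category is the most severe one under a fixed total
order, and the amino-acid consequence is computed on the winning
transcript's spliced CDS.

Splice windows are the two intronic bases adjacent to each exon boundary
— the canonical GT (donor) and AG (acceptor) dinucleotide positions — in
transcription sense.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping
from typing import Optional

from Bio.Seq import Seq

from .annotation_db import (
    ConservationTrack,
    GeneIndex,
    KnownVariantIndex,
    build_gene_index,
    parse_conservation_wiggle,
    parse_gene_table,
    parse_known_variant_table,
    query_known,
    revcomp,
    spliced_cds,
    validate_gene_model,
)
from .models import (
    AnnotatedVariant,
    AnnotationRecord,
    CodonChange,
    FunctionalCategory,
    GeneModel,
    ModelWarning,
    SampleVariant,
    VarAnnotError,
    VariantCall,
    VarType,
    WarningCode,
    resolve_alt_base,
)


@dataclass
class AnnotationDatabase:
    """All loaded resources needed to annotate a variant."""

    reference: Mapping
    models: list[GeneModel]
    gene_index: GeneIndex
    known_index: KnownVariantIndex
    conservation: ConservationTrack
    model_warnings: dict[str, tuple[ModelWarning, ...]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        reference: Mapping,
        models: list[GeneModel],
        known_index: Optional[KnownVariantIndex] = None,
        conservation: Optional[ConservationTrack] = None,
    ) -> "AnnotationDatabase":
        db = cls(
            reference=reference,
            models=models,
            gene_index=build_gene_index(models),
            known_index=known_index or KnownVariantIndex(),
            conservation=conservation or ConservationTrack(),
        )
        for m in models:
            db.model_warnings[m.accession] = tuple(validate_gene_model(m, reference))
        return db

    @classmethod
    def from_texts(
        cls,
        reference: Mapping,
        gene_table: str,
        known_table: str = "",
        wiggle: str = "",
    ) -> "AnnotationDatabase":
        return cls.build(
            reference,
            parse_gene_table(gene_table.splitlines()),
            parse_known_variant_table(known_table.splitlines()),
            parse_conservation_wiggle(wiggle.splitlines()),
        )


def _splice_windows(model: GeneModel) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(donor, acceptor) intronic 2-bp windows in genomic coordinates."""
    donors: list[tuple[int, int]] = []
    acceptors: list[tuple[int, int]] = []
    n = len(model.exons)
    for i, (s, e) in enumerate(model.exons):
        left = (s - 2, s)  # intron immediately 5' (genomic) of this exon
        right = (e, e + 2)  # intron immediately 3' (genomic)
        if model.strand == "+":
            if i > 0:
                acceptors.append(left)
            if i < n - 1:
                donors.append(right)
        else:
            if i > 0:
                donors.append(left)
            if i < n - 1:
                acceptors.append(right)
    return donors, acceptors


def _category_in_model(
    v: VariantCall,
    model: GeneModel,
    reference: Mapping,
) -> FunctionalCategory:
    pos = v.pos
    is_indel = v.var_type is VarType.INDEL
    in_exon = any(s <= pos < e for s, e in model.exons)
    if in_exon:
        if model.cds_start <= pos < model.cds_end and any(
            s <= pos < e for s, e in model.coding_intervals()
        ):
            if is_indel:
                return FunctionalCategory.EXONIC_INDEL
            change = compute_amino_acid_change(v, model, reference)
            if change is not None and change.ref_aa == change.alt_aa:
                return FunctionalCategory.EXONIC_SILENT
            # undeterminable consequence (trailing partial codon of a broken
            # model) is reported at the more severe coding class
            return FunctionalCategory.EXONIC_REPLACEMENT
        if is_indel:
            return FunctionalCategory.UTR_INDEL
        before_cds = pos < model.cds_start
        if (model.strand == "+") == before_cds:
            return FunctionalCategory.UTR5_SNP
        return FunctionalCategory.UTR3_SNP
    donors, acceptors = _splice_windows(model)
    if any(s <= pos < e for s, e in donors):
        return FunctionalCategory.SPLICE_DONOR
    if any(s <= pos < e for s, e in acceptors):
        return FunctionalCategory.SPLICE_ACCEPTOR
    return FunctionalCategory.INTRONIC_INDEL if is_indel else FunctionalCategory.INTRONIC_SNP


def classify_site(
    v: VariantCall,
    index: GeneIndex,
    reference: Mapping,
    log=None,
) -> list[tuple[Optional[GeneModel], FunctionalCategory]]:
    """Classify a variant against every overlapping transcript.

    Returns one (model, category) pair per transcript whose bounds contain
    the variant's first affected base, or a single (None, intergenic) pair
    when nothing overlaps.  A chromosome absent from the gene index is
    intergenic by definition, with a log note.
    """
    intergenic = (
        FunctionalCategory.INTERGENIC_INDEL
        if v.var_type is VarType.INDEL
        else FunctionalCategory.INTERGENIC_SNP
    )
    if not index.has_chrom(v.chrom):
        if log is not None:
            log.warn(f"chromosome {v.chrom} has no gene models; classifying as intergenic")
        return [(None, intergenic)]
    hits = index.query(v.chrom, v.pos, v.pos + 1)
    if not hits:
        return [(None, intergenic)]
    return [(m, _category_in_model(v, m, reference)) for m in hits]


def _cds_offset(model: GeneModel, pos: int) -> Optional[int]:
    """Offset of a genomic position within the spliced CDS (transcript sense)."""
    forward = 0
    total = model.cds_length()
    for s, e in model.coding_intervals():
        if s <= pos < e:
            forward += pos - s
            return forward if model.strand == "+" else total - 1 - forward
        forward += e - s
    return None


def compute_amino_acid_change(
    v: VariantCall,
    model: GeneModel,
    reference: Mapping,
) -> Optional[CodonChange]:
    """Amino-acid consequence of a coding SNP on one transcript.

    The spliced CDS is assembled exon by exon and reverse-complemented for
    '-'-strand models; the codon index is ``offset // 3 + 1``.  A
    heterozygous ambiguity alt is resolved to its non-reference base before
    translation.  Returns None when the variant falls in the trailing
    partial codon of a CDS whose length is not a multiple of 3 (the caller
    leaves the amino-acid fields empty and propagates the model warning).
    """
    if v.var_type is not VarType.SNP:
        raise VarAnnotError("amino-acid change is defined for SNPs only")
    offset = _cds_offset(model, v.pos)
    if offset is None:
        raise VarAnnotError(
            f"{v.chrom}:{v.pos + 1} is not inside the CDS of {model.accession}"
        )
    cds = spliced_cds(model, reference)
    codon_idx = offset // 3
    if 3 * codon_idx + 3 > len(cds):
        return None  # trailing partial codon of a malformed CDS
    alt = resolve_alt_base(v.ref_allele, v.alt_allele)
    if model.strand == "-":
        alt = revcomp(alt)
    codon = cds[3 * codon_idx: 3 * codon_idx + 3]
    within = offset % 3
    alt_codon = codon[:within] + alt + codon[within + 1:]
    return CodonChange(
        ref_aa=str(Seq(codon).translate()),
        aa_pos=codon_idx + 1,
        alt_aa=str(Seq(alt_codon).translate()),
    )


def _collapse(
    entries: list[tuple[Optional[GeneModel], FunctionalCategory]],
) -> tuple[Optional[GeneModel], FunctionalCategory]:
    """Pick the single reported (model, category) by severity, then accession."""
    def sort_key(entry):
        model, category = entry
        return (-category.severity, model.accession if model else "~")

    return min(entries, key=sort_key)


def annotate_variant(sv: SampleVariant, db: AnnotationDatabase, log=None) -> AnnotationRecord:
    """Assemble the full 18-field annotation for one sample variant.

    Per-transcript classifications are collapsed by the fixed severity
    order (ties broken by lowest accession); all overlapping transcript
    accessions are retained in the accession field.  Known-variant fields
    report the catalog record exactly as stored (no strand normalisation);
    a missing conservation score stays empty rather than becoming 0.
    """
    v = sv.variant
    entries = classify_site(v, db.gene_index, db.reference, log=log)
    model, category = _collapse(entries)

    ref_aa, aa_pos, alt_aa = "", None, ""
    warnings: tuple[str, ...] = ()
    gene_name = gene_strand = ""
    refseq_ids: tuple[str, ...] = ()
    if model is not None:
        gene_name = model.gene_name
        gene_strand = model.strand
        refseq_ids = tuple(sorted(m.accession for m, _ in entries if m is not None))
        warnings = tuple(w.code.value for w in db.model_warnings.get(model.accession, ()))
        if category in (FunctionalCategory.EXONIC_REPLACEMENT, FunctionalCategory.EXONIC_SILENT):
            change = compute_amino_acid_change(v, model, db.reference)
            if change is not None:
                ref_aa, aa_pos, alt_aa = change.ref_aa, change.aa_pos, change.alt_aa

    alt_for_lookup = (
        resolve_alt_base(v.ref_allele, v.alt_allele) if v.var_type is VarType.SNP else v.alt_allele
    )
    match = query_known(db.known_index, v.chrom, v.pos, v.ref_allele, alt_for_lookup)

    return AnnotationRecord(
        chrom=v.chrom,
        position=v.pos + 1,
        gene_name=gene_name,
        gene_strand=gene_strand,
        category=category,
        ref_allele=v.ref_allele,
        minor_allele=v.alt_allele,
        var_type=v.var_type,
        ref_aa=ref_aa,
        aa_pos=aa_pos,
        alt_aa=alt_aa,
        warnings=warnings,
        refseq_ids=refseq_ids,
        dbsnp_id=match.record.rsid if match else "",
        dbsnp_allele_mismatch=match.allele_mismatch if match else False,
        dbsnp_heterozygosity=match.record.heterozygosity if match else None,
        dbsnp_orientation=match.record.strand if match else "",
        phastcons=db.conservation.get(v.chrom, v.pos),
        sample_ids=(sv.sample_id,) if sv.sample_id else (),
    )


def annotate_all(
    variants: list[SampleVariant],
    db: AnnotationDatabase,
    log=None,
) -> list[AnnotatedVariant]:
    return [AnnotatedVariant(sv, annotate_variant(sv, db, log=log)) for sv in variants]
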