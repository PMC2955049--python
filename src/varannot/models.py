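"""Core domain types shared across the annotation pipeline.

All genomic coordinates held in these types are 0-based half-open.  The
single exception is :class:`AnnotationRecord.position`, which is reported
1-based because that is what users paste into a genome browser position
box; the conversion happens exactly once, when a record is assembled.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class VarAnnotError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(VarAnnotError):
    """A malformed input row; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class VarType(enum.Enum):
    SNP = "SNP"
    INDEL = "Indel"


class Zygosity(enum.Enum):
    HOM = "HOM"
    HET = "HET"
    UNKNOWN = "UNKNOWN"


class WarningCode(enum.Enum):
    CDS_NOT_MULTIPLE_OF_3 = "CDS_NOT_MULTIPLE_OF_3"
    INTERNAL_STOP = "INTERNAL_STOP"
    MISSING_START = "MISSING_START"
    MISSING_STOP = "MISSING_STOP"
    FRAME_MISMATCH = "FRAME_MISMATCH"
    OUT_OF_BOUNDS = "OUT_OF_BOUNDS"


class FunctionalCategory(enum.Enum):
    """Functional class of a variant site relative to a gene model.

    The enum value is the human-readable label written to output field 5.
    """

    EXONIC_REPLACEMENT = "Exonic Replacement SNP"
    EXONIC_SILENT = "Exonic Silent SNP"
    EXONIC_INDEL = "Exonic Indel"
    SPLICE_DONOR = "Splice Donor"
    SPLICE_ACCEPTOR = "Splice Acceptor"
    UTR5_SNP = "5' UTR SNP"
    UTR3_SNP = "3' UTR SNP"
    UTR_INDEL = "UTR Indel"
    INTRONIC_SNP = "Intronic SNP"
    INTRONIC_INDEL = "Intronic Indel"
    INTERGENIC_SNP = "Intergenic SNP"
    INTERGENIC_INDEL = "Intergenic Indel"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


# Fixed total order used when one variant overlaps several transcripts and a
# single category must be reported.  Higher = more severe.  UTR, intronic and
# intergenic classes are severity ties within their tier.
_SEVERITY = {
    FunctionalCategory.EXONIC_REPLACEMENT: 70,
    FunctionalCategory.EXONIC_INDEL: 60,
    FunctionalCategory.SPLICE_DONOR: 50,
    FunctionalCategory.SPLICE_ACCEPTOR: 45,
    FunctionalCategory.EXONIC_SILENT: 40,
    FunctionalCategory.UTR5_SNP: 30,
    FunctionalCategory.UTR3_SNP: 30,
    FunctionalCategory.UTR_INDEL: 30,
    FunctionalCategory.INTRONIC_SNP: 20,
    FunctionalCategory.INTRONIC_INDEL: 20,
    FunctionalCategory.INTERGENIC_SNP: 10,
    FunctionalCategory.INTERGENIC_INDEL: 10,
}

_CATEGORY_BY_LABEL = {c.value: c for c in FunctionalCategory}


def category_from_label(label: str) -> FunctionalCategory:
    try:
        return _CATEGORY_BY_LABEL[label]
    except KeyError:
        raise VarAnnotError(f"unknown functional category label: {label!r}") from None


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a gene model (genePred dialect, 0-based half-open)."""

    accession: str
    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]
    exon_frames: tuple[int, ...]

    def check(self) -> None:
        """Raise :class:`VarAnnotError` on any structural invariant violation."""
        if self.strand not in ("+", "-"):
            raise VarAnnotError(f"{self.accession}: strand must be '+' or '-'")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise VarAnnotError(
                f"{self.accession}: txStart <= cdsStart <= cdsEnd <= txEnd violated"
            )
        if len(self.exon_frames) != len(self.exons):
            raise VarAnnotError(f"{self.accession}: exonFrames length != exon count")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise VarAnnotError(
                    f"{self.accession}: exon ({s},{e}) outside transcript bounds"
                )
            if prev_end is not None and s < prev_end:
                raise VarAnnotError(f"{self.accession}: exons overlap or are unsorted")
            prev_end = e
        for (s, e), frame in zip(self.exons, self.exon_frames):
            coding = min(e, self.cds_end) - max(s, self.cds_start)
            if coding <= 0 and frame != -1:
                raise VarAnnotError(
                    f"{self.accession}: non-coding exon ({s},{e}) must have frame -1"
                )
            if coding > 0 and frame not in (0, 1, 2):
                raise VarAnnotError(
                    f"{self.accession}: coding exon ({s},{e}) must have frame 0/1/2"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Genomic-order intervals of the CDS portion of each exon."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return out

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.coding_intervals())


@dataclass(frozen=True)
class ModelWarning:
    accession: str
    code: WarningCode
    message: str


@dataclass(frozen=True)
class KnownVariantRecord:
    """A catalog entry for a previously reported variant site.

    ``alleles`` are recorded on the record's own strand; comparisons against
    reference-strand calls must complement them when ``strand`` is '-'.
    """

    rsid: str
    chrom: str
    pos: int
    strand: str
    alleles: frozenset[str]
    heterozygosity: float


@dataclass(frozen=True)
class KnownMatch:
    """Result of a position lookup in the known-variant index."""

    record: KnownVariantRecord
    allele_mismatch: bool


@dataclass(frozen=True)
class VariantCall:
    """One observed variant site.

    ``pos`` is the 0-based first affected reference base; an insertion is
    anchored at the base before the inserted sequence and uses ref '-'; a
    deletion uses alt '-'.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_type: VarType

    def check(self) -> None:
        if self.pos < 0:
            raise VarAnnotError(f"negative position {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise VarAnnotError("reference allele equals minor allele")
        if self.var_type is VarType.SNP:
            if len(self.ref_allele) != 1 or self.ref_allele not in "ACGT":
                raise VarAnnotError(f"SNP ref allele must be one of ACGT: {self.ref_allele!r}")
            if len(self.alt_allele) != 1 or self.alt_allele not in IUPAC_CODES:
                raise VarAnnotError(f"SNP alt allele must be a IUPAC base: {self.alt_allele!r}")
        else:
            if self.ref_allele == "-" and self.alt_allele == "-":
                raise VarAnnotError("indel cannot have '-' for both alleles")


@dataclass(frozen=True)
class SampleVariant:
    """A variant call optionally bound to a sample identifier and zygosity."""

    variant: VariantCall
    sample_id: Optional[str] = None
    zygosity: Zygosity = Zygosity.UNKNOWN


@dataclass(frozen=True)
class CodonChange:
    ref_aa: str
    aa_pos: int  # 1-based codon index in the peptide
    alt_aa: str


@dataclass(frozen=True)
class AnnotationRecord:
    """The 18-field annotated output row.

    Field order matches the tab-delimited output: chromosome, 1-based genome
    position, gene name, gene strand, functional category, reference allele,
    minor allele, variation type, reference amino acid, amino-acid position,
    modified amino acid, warnings, transcript accessions, known-variant id,
    catalog heterozygosity, catalog orientation, conservation score,
    sample ids.
    """

    chrom: str
    position: int  # 1-based
    gene_name: str
    gene_strand: str
    category: FunctionalCategory
    ref_allele: str
    minor_allele: str
    var_type: VarType
    ref_aa: str = ""
    aa_pos: Optional[int] = None
    alt_aa: str = ""
    warnings: tuple[str, ...] = ()
    refseq_ids: tuple[str, ...] = ()
    dbsnp_id: str = ""
    dbsnp_allele_mismatch: bool = False
    dbsnp_heterozygosity: Optional[float] = None
    dbsnp_orientation: str = ""
    phastcons: Optional[float] = None
    sample_ids: tuple[str, ...] = ()

    @property
    def pos0(self) -> int:
        """0-based position (internal convention)."""
        return self.position - 1


@dataclass(frozen=True)
class AnnotatedVariant:
    """A sample variant together with its annotation record."""

    sample_variant: SampleVariant
    record: AnnotationRecord


class InheritanceMode(enum.Enum):
    HOMOZYGOUS = "HOMOZYGOUS"
    COMPOUND_HET = "COMPOUND_HET"


@dataclass(frozen=True)
class RecessiveLocusCall:
    sample_id: str
    gene_name: str
    mode: InheritanceMode
    supporting_variants: tuple[AnnotationRecord, ...]


# IUPAC nucleotide ambiguity codes.  Two-base codes double as the encoding of
# heterozygous SNP calls (code covering the reference plus one other base).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CODE_BY_PAIR = {bases: code for code, bases in IUPAC_CODES.items() if len(bases) == 2}


def iupac_code_for(a: str, b: str) -> str:
    """The two-base ambiguity code covering bases ``a`` and ``b``."""
    try:
        return _CODE_BY_PAIR[frozenset((a, b))]
    except KeyError:
        raise VarAnnotError(f"no two-base IUPAC code for {a}/{b}") from None


def infer_zygosity(ref: str, alt: str) -> Zygosity:
    """Zygosity implied by the allele encoding of a SNP call.

    A two-base ambiguity code covering the reference plus one other base
    means heterozygous; a plain non-reference base means homozygous; any
    other encoding (indels, wider codes) is unknown.
    """
    bases = IUPAC_CODES.get(alt)
    if bases is None:
        return Zygosity.UNKNOWN
    if len(bases) == 1:
        return Zygosity.HOM if alt != ref else Zygosity.UNKNOWN
    if len(bases) == 2 and ref in bases:
        return Zygosity.HET
    return Zygosity.UNKNOWN


def resolve_alt_base(ref: str, alt: str) -> str:
    """Resolve a heterozygous ambiguity code to its non-reference base.

    Plain bases pass through unchanged.
    """
    bases = IUPAC_CODES.get(alt)
    if bases is None or len(bases) == 1:
        return alt
    others = bases - {ref}
    if len(others) == 1:
        return next(iter(others))
    return alt
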