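"""Serialization of annotation results: the 18-column table, a
browser-loadable BED track, category tallies and the run log."""
from __future__ import annotations

from collections.abc import Iterable
from typing import Optional

from .models import (
    AnnotationRecord,
    FunctionalCategory,
    ParseError,
    VarType,
    category_from_label,
)

ANNOTATION_HEADER = [
    "Chromosome",
    "Genome Position",
    "Gene Name",
    "Gene Strand",
    "Functional Category",
    "Reference Allele",
    "Minor Allele",
    "Variation Type",
    "Reference Amino Acid",
    "Amino Acid Position",
    "Modified Amino Acid",
    "Warnings",
    "RefSeq ID",
    "dbSNP ID",
    "dbSNP Heterozygosity",
    "dbSNP Orientation",
    "PhastCons Score",
    "Sample IDs",
]

_MISMATCH_SUFFIX = "|allele_mismatch"


def _fmt_float(x: Optional[float]) -> str:
    return "" if x is None else repr(x)


def record_to_row(r: AnnotationRecord) -> list[str]:
    dbsnp = r.dbsnp_id + (_MISMATCH_SUFFIX if r.dbsnp_id and r.dbsnp_allele_mismatch else "")
    return [
        r.chrom,
        str(r.position),
        r.gene_name,
        r.gene_strand,
        r.category.value,
        r.ref_allele,
        r.minor_allele,
        r.var_type.value,
        r.ref_aa,
        "" if r.aa_pos is None else str(r.aa_pos),
        r.alt_aa,
        ";".join(r.warnings),
        ";".join(r.refseq_ids),
        dbsnp,
        _fmt_float(r.dbsnp_heterozygosity),
        r.dbsnp_orientation,
        _fmt_float(r.phastcons),
        ";".join(r.sample_ids),
    ]


def row_to_record(row: list[str], lineno: Optional[int] = None) -> AnnotationRecord:
    if len(row) != len(ANNOTATION_HEADER):
        raise ParseError(
            f"expected {len(ANNOTATION_HEADER)} columns, got {len(row)}", lineno
        )
    dbsnp = row[13]
    mismatch = dbsnp.endswith(_MISMATCH_SUFFIX)
    if mismatch:
        dbsnp = dbsnp[: -len(_MISMATCH_SUFFIX)]
    return AnnotationRecord(
        chrom=row[0],
        position=int(row[1]),
        gene_name=row[2],
        gene_strand=row[3],
        category=category_from_label(row[4]),
        ref_allele=row[5],
        minor_allele=row[6],
        var_type=VarType(row[7]),
        ref_aa=row[8],
        aa_pos=int(row[9]) if row[9] else None,
        alt_aa=row[10],
        warnings=tuple(w for w in row[11].split(";") if w),
        refseq_ids=tuple(a for a in row[12].split(";") if a),
        dbsnp_id=dbsnp,
        dbsnp_allele_mismatch=mismatch,
        dbsnp_heterozygosity=float(row[14]) if row[14] else None,
        dbsnp_orientation=row[15],
        phastcons=float(row[16]) if row[16] else None,
        sample_ids=tuple(s for s in row[17].split(";") if s),
    )


def write_annotation_table(records: Iterable[AnnotationRecord], stream) -> None:
    """Tab-delimited table: header row plus one row per record, input order."""
    stream.write("\t".join(ANNOTATION_HEADER) + "\n")
    for r in records:
        stream.write("\t".join(record_to_row(r)) + "\n")


def read_annotation_table(lines: Iterable[str]) -> list[AnnotationRecord]:
    """Inverse of :func:`write_annotation_table`."""
    records = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if lineno == 1:
            if line.split("\t") != ANNOTATION_HEADER:
                raise ParseError("unexpected annotation table header", lineno)
            continue
        if not line.strip():
            continue
        records.append(row_to_record(line.split("\t"), lineno))
    return records


def merge_by_site(records: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Merge records identical except for sample ids, pooling the id lists.

    Used for the final table so one site carried by several samples prints
    once with all its sample ids.
    """
    merged: dict[tuple, AnnotationRecord] = {}
    order: list[tuple] = []
    for r in records:
        key = tuple(record_to_row(r)[:17])
        if key in merged:
            prev = merged[key]
            ids = tuple(sorted(set(prev.sample_ids) | set(r.sample_ids)))
            merged[key] = AnnotationRecord(**{**prev.__dict__, "sample_ids": ids})
        else:
            merged[key] = r
            order.append(key)
    return [merged[k] for k in order]


def bed_interval(r: AnnotationRecord) -> tuple[int, int]:
    """0-based half-open interval of a record (insertion anchors one base)."""
    start = r.position - 1
    if r.ref_allele == "-":
        return start, start + 1
    return start, start + len(r.ref_allele)


def write_bed(records: Iterable[AnnotationRecord], stream) -> None:
    """4-column BED: chrom, 0-based start, end, name (gene|category|ref>alt)."""
    rows = []
    for r in records:
        start, end = bed_interval(r)
        name = f"{r.gene_name or '.'}|{r.category.value}|{r.ref_allele}>{r.minor_allele}"
        rows.append((r.chrom, start, end, name))
    rows.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    for chrom, start, end, name in rows:
        stream.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# Summary taxonomy: splice sites fold into the intronic tallies and the two
# UTR sides pool, giving nine rows.
TALLY_CATEGORIES = [
    "Exonic Replacement SNPs",
    "Exonic Silent SNPs",
    "Exonic Indel Sites",
    "UTR SNPs",
    "UTR Indels",
    "Intronic SNPs",
    "Intronic Indel Sites",
    "Intergenic SNPs",
    "Intergenic Indel Sites",
]

_TALLY_MAP = {
    FunctionalCategory.EXONIC_REPLACEMENT: "Exonic Replacement SNPs",
    FunctionalCategory.EXONIC_SILENT: "Exonic Silent SNPs",
    FunctionalCategory.EXONIC_INDEL: "Exonic Indel Sites",
    FunctionalCategory.UTR5_SNP: "UTR SNPs",
    FunctionalCategory.UTR3_SNP: "UTR SNPs",
    FunctionalCategory.UTR_INDEL: "UTR Indels",
    FunctionalCategory.INTRONIC_SNP: "Intronic SNPs",
    FunctionalCategory.INTRONIC_INDEL: "Intronic Indel Sites",
    FunctionalCategory.INTERGENIC_SNP: "Intergenic SNPs",
    FunctionalCategory.INTERGENIC_INDEL: "Intergenic Indel Sites",
}


def tally_categories(records: Iterable[AnnotationRecord]) -> dict[str, int]:
    """Category counts in the pooled nine-row taxonomy (a partition)."""
    counts = {name: 0 for name in TALLY_CATEGORIES}
    for r in records:
        category = r.category
        if category in (FunctionalCategory.SPLICE_DONOR, FunctionalCategory.SPLICE_ACCEPTOR):
            name = "Intronic Indel Sites" if r.var_type is VarType.INDEL else "Intronic SNPs"
        else:
            name = _TALLY_MAP[category]
        counts[name] += 1
    return counts


class RunLog:
    """Ordered (severity, message) entries describing one run."""

    def __init__(self) -> None:
        self.entries: list[tuple[str, str]] = []

    def info(self, message: str) -> None:
        self.entries.append(("INFO", message))

    def warn(self, message: str) -> None:
        self.entries.append(("WARN", message))

    def error(self, message: str) -> None:
        self.entries.append(("ERROR", message))

    def write(self, stream) -> None:
        for severity, message in self.entries:
            stream.write(f"{severity}\t{message}\n")

    def count(self, severity: str) -> int:
        return sum(1 for s, _ in self.entries if s == severity)
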