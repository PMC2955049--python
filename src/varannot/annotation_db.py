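"""Positional databases backing annotation queries.

Three external resource tables are parsed into in-memory indexes: gene
models (genePred dialect), known-variant catalogs (dbSNP dialect) and
per-base conservation tracks (wiggle).  The contract of each index is
query equivalence with a linear scan of the parsed rows, not any
particular storage layout.

Coordinate conventions: genePred and BED inputs are natively 0-based
half-open and are stored as-is; wiggle declarations are 1-based per the
format standard and are converted to 0-based at parse time.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Optional

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .models import (
    GeneModel,
    KnownMatch,
    KnownVariantRecord,
    ModelWarning,
    ParseError,
    VarAnnotError,
    WarningCode,
)

GENE_TABLE_COLUMNS = 12  # accession .. exonFrames, see parse_gene_table
MISSING_SCORE = None  # sentinel for positions absent from a conservation track

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# reference sequence access


def load_reference(path: str):
    """Open an indexed FASTA reference (uppercase, raw-string access)."""
    from pyfaidx import Fasta

    return Fasta(path, as_raw=True, sequence_always_upper=True)


def fetch(reference: Mapping, chrom: str, start: int, end: int) -> str:
    """Uppercase reference slice; works for plain dicts and indexed FASTA."""
    return str(reference[chrom][start:end]).upper()


def chrom_length(reference: Mapping, chrom: str) -> int:
    return len(reference[chrom])


def has_chrom(reference: Mapping, chrom: str) -> bool:
    return chrom in set(reference.keys())


# ---------------------------------------------------------------------------
# gene models


def _int_field(token: str, what: str, line_number: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {token!r}", line_number) from None


def _int_list(token: str, what: str, line_number: int) -> tuple[int, ...]:
    items = [t for t in token.strip().split(",") if t != ""]
    return tuple(_int_field(t, what, line_number) for t in items)


def parse_gene_table(lines: Iterable[str]) -> list[GeneModel]:
    """Parse a tab-delimited genePred-dialect gene table.

    Columns: accession, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds, geneName, exonFrames.  The exon lists
    are comma-separated (trailing comma tolerated, as written by the UCSC
    table browser).  Blank lines and ``#`` comments are skipped.
    """
    models: list[GeneModel] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != GENE_TABLE_COLUMNS:
            raise ParseError(
                f"expected {GENE_TABLE_COLUMNS} columns, got {len(fields)}", lineno
            )
        (acc, chrom, strand, tx_s, tx_e, cds_s, cds_e,
         exon_count, exon_starts, exon_ends, gene_name, exon_frames) = fields
        n = _int_field(exon_count, "exonCount", lineno)
        starts = _int_list(exon_starts, "exonStarts", lineno)
        ends = _int_list(exon_ends, "exonEnds", lineno)
        frames = _int_list(exon_frames, "exonFrames", lineno)
        if len(starts) != n or len(ends) != n or len(frames) != n:
            raise ParseError(
                f"exonCount {n} does not match exon list lengths "
                f"({len(starts)} starts, {len(ends)} ends, {len(frames)} frames)",
                lineno,
            )
        model = GeneModel(
            accession=acc,
            gene_name=gene_name,
            chrom=chrom,
            strand=strand,
            tx_start=_int_field(tx_s, "txStart", lineno),
            tx_end=_int_field(tx_e, "txEnd", lineno),
            cds_start=_int_field(cds_s, "cdsStart", lineno),
            cds_end=_int_field(cds_e, "cdsEnd", lineno),
            exons=tuple(zip(starts, ends)),
            exon_frames=frames,
        )
        try:
            model.check()
        except VarAnnotError as exc:
            raise ParseError(str(exc), lineno) from None
        models.append(model)
    return models


def serialize_gene_table(models: Iterable[GeneModel]) -> str:
    """Inverse of :func:`parse_gene_table` (round-trips all fields)."""
    rows = []
    for m in models:
        rows.append("\t".join([
            m.accession, m.chrom, m.strand,
            str(m.tx_start), str(m.tx_end), str(m.cds_start), str(m.cds_end),
            str(len(m.exons)),
            "".join(f"{s}," for s, _ in m.exons),
            "".join(f"{e}," for _, e in m.exons),
            m.gene_name,
            "".join(f"{f}," for f in m.exon_frames),
        ]))
    return "\n".join(rows) + ("\n" if rows else "")


class GeneIndex:
    """Per-chromosome interval index over transcript bounds."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, model: GeneModel) -> None:
        self._trees.setdefault(model.chrom, IntervalTree()).addi(
            model.tx_start, model.tx_end, model
        )

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """All models whose transcript interval overlaps [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda m: (m.tx_start, m.tx_end, m.accession))
        return hits

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def build_gene_index(models: Iterable[GeneModel]) -> GeneIndex:
    index = GeneIndex()
    seen: set[tuple[str, str, int]] = set()
    for m in models:
        key = (m.accession, m.chrom, m.tx_start)
        if key in seen:
            raise VarAnnotError(f"duplicate gene model {key}: ambiguous")
        seen.add(key)
        index.add(m)
    return index


def spliced_cds(model: GeneModel, reference: Mapping) -> str:
    """The spliced coding sequence in transcription orientation."""
    pieces = [fetch(reference, model.chrom, s, e) for s, e in model.coding_intervals()]
    seq = "".join(pieces)
    return revcomp(seq) if model.strand == "-" else seq


def expected_exon_frames(model: GeneModel) -> tuple[int, ...]:
    """Per-exon frames implied by cumulative coding length (genePred rule).

    The frame of an exon is the number of coding bases in transcript-earlier
    exons mod 3; exons with no coding bases get -1.
    """
    coding_len = [min(e, model.cds_end) - max(s, model.cds_start) for s, e in model.exons]
    coding_len = [max(0, c) for c in coding_len]
    n = len(model.exons)
    frames = []
    for i in range(n):
        if coding_len[i] == 0:
            frames.append(-1)
        elif model.strand == "+":
            frames.append(sum(coding_len[:i]) % 3)
        else:
            frames.append(sum(coding_len[i + 1:]) % 3)
    return tuple(frames)


def validate_gene_model(model: GeneModel, reference: Mapping) -> list[ModelWarning]:
    """Sanity-check a gene model against the reference sequence.

    Returns all applicable warnings; an empty list means the spliced CDS is a
    multiple of 3, begins with the initiator codon, ends with a stop, has no
    internal stop, the stored exon frames agree with cumulative CDS length,
    and all coordinates lie on the chromosome.
    """
    if not has_chrom(reference, model.chrom):
        raise VarAnnotError(f"chromosome {model.chrom} absent from reference")
    warnings: list[ModelWarning] = []

    def warn(code: WarningCode, message: str) -> None:
        warnings.append(ModelWarning(model.accession, code, message))

    clen = chrom_length(reference, model.chrom)
    if model.tx_start < 0 or model.tx_end > clen:
        warn(
            WarningCode.OUT_OF_BOUNDS,
            f"transcript [{model.tx_start},{model.tx_end}) outside chromosome of length {clen}",
        )
        return warnings  # cannot safely read sequence past the chromosome end

    if expected_exon_frames(model) != model.exon_frames:
        warn(
            WarningCode.FRAME_MISMATCH,
            f"stored exonFrames {model.exon_frames} != expected {expected_exon_frames(model)}",
        )

    if not model.is_coding:
        return warnings

    cds = spliced_cds(model, reference)
    if len(cds) % 3 != 0:
        warn(
            WarningCode.CDS_NOT_MULTIPLE_OF_3,
            f"spliced CDS length {len(cds)} is not a multiple of 3",
        )
    n_codons = len(cds) // 3
    if n_codons == 0:
        return warnings
    protein = str(Seq(cds[: 3 * n_codons]).translate())
    if not cds.startswith("ATG"):
        warn(WarningCode.MISSING_START, f"CDS starts with {cds[:3]}, not ATG")
    if protein[-1] != "*":
        warn(WarningCode.MISSING_STOP, f"CDS ends with {cds[3 * n_codons - 3: 3 * n_codons]}, not a stop codon")
    if "*" in protein[:-1]:
        warn(
            WarningCode.INTERNAL_STOP,
            f"internal stop codon at peptide position {protein.index('*') + 1}",
        )
    return warnings


# ---------------------------------------------------------------------------
# known variants

KNOWN_TABLE_COLUMNS = 6  # rsid, chrom, pos, strand, alleles, heterozygosity


class KnownVariantIndex:
    """Exact-position lookup over known-variant records."""

    def __init__(self) -> None:
        self._by_pos: dict[str, dict[int, list[KnownVariantRecord]]] = {}

    def add(self, record: KnownVariantRecord) -> None:
        self._by_pos.setdefault(record.chrom, {}).setdefault(record.pos, []).append(record)

    def at(self, chrom: str, pos: int) -> list[KnownVariantRecord]:
        return list(self._by_pos.get(chrom, {}).get(pos, []))

    def __len__(self) -> int:
        return sum(len(v) for c in self._by_pos.values() for v in c.values())


def parse_known_variant_table(lines: Iterable[str]) -> KnownVariantIndex:
    """Parse a tab-delimited known-variant table into a positional index.

    Columns: rsid, chrom, pos (0-based), strand, alleles ("A/T" style,
    recorded on the record's strand), heterozygosity in [0, 1].
    """
    index = KnownVariantIndex()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != KNOWN_TABLE_COLUMNS:
            raise ParseError(
                f"expected {KNOWN_TABLE_COLUMNS} columns, got {len(fields)}", lineno
            )
        rsid, chrom, pos, strand, alleles, het = fields
        if strand not in ("+", "-"):
            raise ParseError(f"strand must be '+' or '-', got {strand!r}", lineno)
        allele_set = frozenset(a.strip().upper() for a in alleles.split("/") if a.strip())
        if not allele_set:
            raise ParseError("empty allele set", lineno)
        try:
            het_value = float(het)
        except ValueError:
            raise ParseError(f"non-numeric heterozygosity: {het!r}", lineno) from None
        if not 0.0 <= het_value <= 1.0:
            raise ParseError(f"heterozygosity {het_value} outside [0, 1]", lineno)
        index.add(
            KnownVariantRecord(
                rsid=rsid,
                chrom=chrom,
                pos=_int_field(pos, "position", lineno),
                strand=strand,
                alleles=allele_set,
                heterozygosity=het_value,
            )
        )
    return index


def _oriented_alleles(record: KnownVariantRecord) -> frozenset[str]:
    """Record alleles expressed on the reference '+' strand."""
    if record.strand == "+":
        return record.alleles
    return frozenset("-" if a == "-" else revcomp(a) for a in record.alleles)


def query_known(
    index: KnownVariantIndex,
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
) -> Optional[KnownMatch]:
    """Look up a variant in the known catalog by exact position.

    Record alleles are complemented onto the reference strand when the record
    is stored on '-' before comparison; the record itself is returned as
    stored.  A position hit whose allele set does not contain both query
    alleles is returned with ``allele_mismatch=True`` so that downstream
    novelty filtering can still see that the position was reported.
    """
    records = index.at(chrom, pos)
    if not records:
        return None
    query = {ref_allele.upper(), alt_allele.upper()}
    for record in records:
        if query <= _oriented_alleles(record):
            return KnownMatch(record=record, allele_mismatch=False)
    return KnownMatch(record=records[0], allele_mismatch=True)


# ---------------------------------------------------------------------------
# conservation track


class ConservationTrack:
    """Sparse per-base conservation scores (phastCons probabilities).

    Positions never declared in the source track return ``None``; a missing
    score is distinct from a score of 0.
    """

    def __init__(self) -> None:
        self._scores: dict[str, dict[int, float]] = {}

    def set(self, chrom: str, pos: int, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise VarAnnotError(f"conservation score {score} outside [0, 1]")
        self._scores.setdefault(chrom, {})[pos] = score

    def get(self, chrom: str, pos: int) -> Optional[float]:
        return self._scores.get(chrom, {}).get(pos, MISSING_SCORE)

    def __len__(self) -> int:
        return sum(len(v) for v in self._scores.values())


def _parse_declaration(line: str, lineno: int) -> dict[str, str]:
    parts = line.split()
    kv = {}
    for token in parts[1:]:
        if "=" not in token:
            raise ParseError(f"malformed declaration token {token!r}", lineno)
        k, v = token.split("=", 1)
        kv[k] = v
    return kv


def parse_conservation_wiggle(lines: Iterable[str]) -> ConservationTrack:
    """Parse a wiggle stream (fixedStep and/or variableStep sections).

    Wiggle declarations are 1-based; stored positions are converted to
    0-based.  ``span`` assigns a value to that many consecutive bases.
    Scores must lie in [0, 1].
    """
    track = ConservationTrack()
    mode: Optional[str] = None
    chrom = ""
    next_pos = 0
    step = 1
    span = 1
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        first = line.split()[0]
        if first == "fixedStep":
            kv = _parse_declaration(line, lineno)
            try:
                chrom = kv["chrom"]
                next_pos = int(kv["start"]) - 1  # 1-based -> 0-based
            except (KeyError, ValueError):
                raise ParseError("fixedStep requires chrom= and integer start=", lineno) from None
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            mode = "fixed"
            continue
        if first == "variableStep":
            kv = _parse_declaration(line, lineno)
            if "chrom" not in kv:
                raise ParseError("variableStep requires chrom=", lineno)
            chrom = kv["chrom"]
            span = int(kv.get("span", 1))
            mode = "variable"
            continue
        if not line[0].isdigit() and line[0] not in "+-.":
            raise ParseError(f"unknown declaration keyword {first!r}", lineno)
        if mode is None:
            raise ParseError("data line before any fixedStep/variableStep declaration", lineno)
        tokens = line.split()
        if mode == "fixed":
            if len(tokens) != 1:
                raise ParseError("fixedStep data lines carry a single value", lineno)
            score = _parse_score(tokens[0], lineno)
            for offset in range(span):
                track.set(chrom, next_pos + offset, score)
            next_pos += step
        else:
            if len(tokens) != 2:
                raise ParseError("variableStep data lines carry position and value", lineno)
            try:
                pos = int(tokens[0]) - 1  # 1-based -> 0-based
            except ValueError:
                raise ParseError(f"non-integer position {tokens[0]!r}", lineno) from None
            score = _parse_score(tokens[1], lineno)
            for offset in range(span):
                track.set(chrom, pos + offset, score)
    return track


def _parse_score(token: str, lineno: int) -> float:
    try:
        score = float(token)
    except ValueError:
        raise ParseError(f"non-numeric score {token!r}", lineno) from None
    if not 0.0 <= score <= 1.0:
        raise ParseError(f"score {score} outside [0, 1]", lineno)
    return score
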