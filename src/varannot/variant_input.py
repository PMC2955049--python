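"""Readers for the four variant input formats.

1. Reference FASTA + multi-FASTA sequence fragments + a BED file mapping
   each fragment onto the reference (variants are derived by comparison).
2. A list-of-variants TSV.
3. The same list with a leading sample-ID column.
4. A single variant given directly.

List positions are 1-based (genome-browser display convention) and are
converted to the internal 0-based convention here; BED rows are natively
0-based half-open.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Optional

from Bio import SeqIO

from .models import (
    IUPAC_CODES,
    ParseError,
    SampleVariant,
    VarAnnotError,
    VariantCall,
    VarType,
    Zygosity,
    infer_zygosity,
)
from .annotation_db import fetch, has_chrom

_TYPE_TOKENS = {"snp": VarType.SNP, "indel": VarType.INDEL}


def _parse_type(token: str, lineno: Optional[int] = None) -> VarType:
    try:
        return _TYPE_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(f"variation type must be SNP or Indel, got {token!r}", lineno) from None


def _make_call(
    chrom: str,
    pos1: int,
    ref: str,
    alt: str,
    var_type: VarType,
    lineno: Optional[int] = None,
) -> VariantCall:
    if pos1 < 1:
        raise ParseError(f"position {pos1} is not a valid 1-based coordinate", lineno)
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    if ref == alt:
        raise ParseError("reference allele equals minor allele", lineno)
    call = VariantCall(chrom=chrom, pos=pos1 - 1, ref_allele=ref, alt_allele=alt, var_type=var_type)
    try:
        call.check()
    except VarAnnotError as exc:
        raise ParseError(str(exc), lineno) from None
    return call


def parse_variant_list(
    lines: Iterable[str],
    with_samples: bool = False,
    log=None,
) -> list[SampleVariant]:
    """Parse a list-of-variants TSV.

    Columns: [sample_id,] chrom, genome position (1-based), fragment-relative
    position, reference allele, minor allele, type (SNP/Indel).  The
    fragment-relative column is accepted but carries no annotation output.
    Duplicate (sample, chrom, pos) rows are dropped with a log warning.
    Zygosity is inferred from the allele encoding: a two-base ambiguity code
    covering the reference means heterozygous, a plain base homozygous.
    """
    expected = 7 if with_samples else 6
    out: list[SampleVariant] = []
    seen: set[tuple[Optional[str], str, int]] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != expected:
            raise ParseError(f"expected {expected} columns, got {len(fields)}", lineno)
        sample_id = fields[0].strip() if with_samples else None
        chrom, pos1, _frag_pos, ref, alt, type_token = fields[-6:]
        try:
            pos1_value = int(pos1)
        except ValueError:
            raise ParseError(f"non-numeric position {pos1!r}", lineno) from None
        call = _make_call(chrom.strip(), pos1_value, ref, alt, _parse_type(type_token, lineno), lineno)
        key = (sample_id, call.chrom, call.pos)
        if key in seen:
            if log is not None:
                log.warn(f"duplicate variant row dropped: sample={sample_id} {call.chrom}:{pos1_value}")
            continue
        seen.add(key)
        zygosity = (
            infer_zygosity(call.ref_allele, call.alt_allele)
            if call.var_type is VarType.SNP
            else Zygosity.UNKNOWN
        )
        out.append(SampleVariant(variant=call, sample_id=sample_id, zygosity=zygosity))
    return out


def serialize_variant_list(variants: Iterable[SampleVariant], with_samples: bool = False) -> str:
    """Inverse of :func:`parse_variant_list` (fragment-relative column written as 0)."""
    rows = []
    for sv in variants:
        v = sv.variant
        fields = [v.chrom, str(v.pos + 1), "0", v.ref_allele, v.alt_allele, v.var_type.value]
        if with_samples:
            fields.insert(0, sv.sample_id or "")
        rows.append("\t".join(fields))
    return "\n".join(rows) + ("\n" if rows else "")


def parse_single_variant(
    chrom: str,
    pos: int,
    var_type: str,
    ref_allele: str,
    alt_allele: str,
    sample_id: Optional[str] = None,
) -> SampleVariant:
    """Build one variant from command-line style arguments (1-based position)."""
    call = _make_call(chrom, pos, ref_allele, alt_allele, _parse_type(var_type))
    zygosity = (
        infer_zygosity(call.ref_allele, call.alt_allele)
        if call.var_type is VarType.SNP
        else Zygosity.UNKNOWN
    )
    return SampleVariant(variant=call, sample_id=sample_id, zygosity=zygosity)


def read_fasta(handle) -> dict[str, str]:
    """Read a (multi-)FASTA stream into an uppercase name -> sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def parse_bed_mapping(lines: Iterable[str]) -> list[tuple[str, int, int, str]]:
    """Parse BED rows (chrom, start, end, name) mapping fragments to the genome."""
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"BED mapping rows need chrom, start, end, name; got {len(fields)} columns", lineno)
        chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
        try:
            s, e = int(start), int(end)
        except ValueError:
            raise ParseError(f"non-numeric BED coordinates {start!r}/{end!r}", lineno) from None
        if not 0 <= s < e:
            raise ParseError(f"invalid BED interval [{s},{e})", lineno)
        rows.append((chrom, s, e, name))
    return rows


def call_variants_from_fragments(
    reference: Mapping,
    fragments: Mapping[str, str],
    mapping: list[tuple[str, int, int, str]],
    log=None,
) -> list[SampleVariant]:
    """Derive variants by comparing aligned fragments against the reference.

    Each mapping row places one fragment record over a reference interval of
    the same length; ``-`` in the fragment marks a deleted reference base
    (runs of adjacent gaps merge into one deletion), any other mismatching
    base is a SNP (ambiguity codes covering the reference are heterozygous).
    Insertions cannot be expressed in this dialect and must come through the
    list formats.  Identical calls produced by overlapping fragments are
    deduplicated with a log entry; output is in genomic order.
    """
    calls: list[SampleVariant] = []
    seen: set[tuple[str, int, str, str]] = set()

    def emit(call: VariantCall, zygosity: Zygosity) -> None:
        key = (call.chrom, call.pos, call.ref_allele, call.alt_allele)
        if key in seen:
            if log is not None:
                log.warn(
                    f"duplicate call from overlapping fragments dropped: "
                    f"{call.chrom}:{call.pos + 1} {call.ref_allele}>{call.alt_allele}"
                )
            return
        seen.add(key)
        calls.append(SampleVariant(variant=call, sample_id=None, zygosity=zygosity))

    for chrom, start, end, name in mapping:
        if name not in fragments:
            raise VarAnnotError(f"BED name {name!r} has no matching FASTA record")
        if not has_chrom(reference, chrom):
            raise VarAnnotError(f"chromosome {chrom} absent from reference")
        frag = fragments[name].upper()
        if len(frag) != end - start:
            raise VarAnnotError(
                f"fragment {name!r} length {len(frag)} != BED interval length {end - start}"
            )
        ref_seq = fetch(reference, chrom, start, end)
        del_start: Optional[int] = None  # open deletion run, genomic start
        for i, frag_base in enumerate(frag):
            gpos = start + i
            ref_base = ref_seq[i]
            if frag_base == "-":
                if del_start is None:
                    del_start = gpos
                continue
            if del_start is not None:
                emit(
                    VariantCall(chrom, del_start, ref_seq[del_start - start: gpos - start], "-", VarType.INDEL),
                    Zygosity.UNKNOWN,
                )
                del_start = None
            if frag_base != ref_base:
                if frag_base not in IUPAC_CODES:
                    raise VarAnnotError(f"fragment {name!r}: unexpected character {frag_base!r}")
                emit(
                    VariantCall(chrom, gpos, ref_base, frag_base, VarType.SNP),
                    infer_zygosity(ref_base, frag_base),
                )
        if del_start is not None:
            emit(
                VariantCall(chrom, del_start, ref_seq[del_start - start:], "-", VarType.INDEL),
                Zygosity.UNKNOWN,
            )
    calls.sort(key=lambda sv: (sv.variant.chrom, sv.variant.pos, sv.variant.alt_allele))
    return calls
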