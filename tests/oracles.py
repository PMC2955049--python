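"""Independent brute-force oracles.

Deliberately written without reusing the package's classification or CDS
arithmetic: regions are materialised as explicit per-position sets, the
spliced CDS is assembled by enumerating coding genomic positions one by
one, and translation goes through the raw standard codon table.  Only
shared constants (the genetic code, the severity order as specified) are
common with the implementation.
"""
from __future__ import annotations

from functools import lru_cache
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

from varannot.models import FunctionalCategory as FC
from varannot.models import GeneModel, VariantCall, VarType

_TABLE = unambiguous_dna_by_id[1]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_IUPAC_PAIRS = {
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"},
    "W": {"A", "T"}, "K": {"G", "T"}, "M": {"A", "C"},
}

# severity order restated from the contract, most to least severe
_ORACLE_ORDER = [
    [FC.EXONIC_REPLACEMENT],
    [FC.EXONIC_INDEL],
    [FC.SPLICE_DONOR],
    [FC.SPLICE_ACCEPTOR],
    [FC.EXONIC_SILENT],
    [FC.UTR5_SNP, FC.UTR3_SNP, FC.UTR_INDEL],
    [FC.INTRONIC_SNP, FC.INTRONIC_INDEL],
    [FC.INTERGENIC_SNP, FC.INTERGENIC_INDEL],
]
_ORACLE_RANK = {c: i for i, tier in enumerate(_ORACLE_ORDER) for c in tier}


def translate_codon(codon: str) -> str:
    return "*" if codon in _TABLE.stop_codons else _TABLE.forward_table[codon]


def resolve_het(ref: str, alt: str) -> str:
    pair = _IUPAC_PAIRS.get(alt)
    if pair and ref in pair:
        (other,) = pair - {ref}
        return other
    return alt


@lru_cache(maxsize=None)
def region_sets(model: GeneModel) -> dict[str, set[int]]:
    """Materialise every structural region of a transcript as position sets."""
    exonic: set[int] = set()
    for s, e in model.exons:
        exonic.update(range(s, e))
    coding = {p for p in exonic if model.cds_start <= p < model.cds_end}
    donor: set[int] = set()
    acceptor: set[int] = set()
    for (_, prev_end), (next_start, _) in zip(model.exons, model.exons[1:]):
        if model.strand == "+":
            donor.update((prev_end, prev_end + 1))
            acceptor.update((next_start - 2, next_start - 1))
        else:
            donor.update((next_start - 2, next_start - 1))
            acceptor.update((prev_end, prev_end + 1))
    if model.strand == "+":
        utr5 = {p for p in exonic - coding if p < model.cds_start}
        utr3 = {p for p in exonic - coding if p >= model.cds_end}
    else:
        utr5 = {p for p in exonic - coding if p >= model.cds_end}
        utr3 = {p for p in exonic - coding if p < model.cds_start}
    return {
        "exonic": exonic, "coding": coding, "donor": donor,
        "acceptor": acceptor, "utr5": utr5, "utr3": utr3,
    }


@lru_cache(maxsize=None)
def coding_positions_tx_order(model: GeneModel) -> list[int]:
    """Genomic positions of the CDS listed in transcription order."""
    positions: list[int] = []
    for s, e in model.exons:
        positions.extend(
            p for p in range(s, e) if model.cds_start <= p < model.cds_end
        )
    return positions if model.strand == "+" else positions[::-1]


def oracle_codon_change(
    v: VariantCall, model: GeneModel, reference
) -> Optional[tuple[str, int, str]]:
    """(ref_aa, aa_pos, alt_aa) by mutating and translating the whole CDS."""
    positions = coding_positions_tx_order(model)
    offset = positions.index(v.pos)
    seq = str(reference[model.chrom][:]).upper()
    tx_base = lambda p: seq[p] if model.strand == "+" else _COMP[seq[p]]
    cds = "".join(tx_base(p) for p in positions)
    alt = resolve_het(v.ref_allele, v.alt_allele)
    if model.strand == "-":
        alt = _COMP[alt]
    mutated = cds[:offset] + alt + cds[offset + 1:]
    k = offset // 3
    if 3 * k + 3 > len(cds):
        return None
    ref_prot = [translate_codon(cds[3 * i: 3 * i + 3]) for i in range(len(cds) // 3)]
    alt_prot = [translate_codon(mutated[3 * i: 3 * i + 3]) for i in range(len(mutated) // 3)]
    return (ref_prot[k], k + 1, alt_prot[k])


def oracle_category_in_model(
    v: VariantCall, model: GeneModel, reference
) -> FC:
    pos = v.pos
    sets = region_sets(model)
    is_indel = v.var_type is VarType.INDEL
    if pos in sets["coding"]:
        if is_indel:
            return FC.EXONIC_INDEL
        change = oracle_codon_change(v, model, reference)
        if change is not None and change[0] == change[2]:
            return FC.EXONIC_SILENT
        return FC.EXONIC_REPLACEMENT
    if pos in sets["exonic"]:
        if is_indel:
            return FC.UTR_INDEL
        return FC.UTR5_SNP if pos in sets["utr5"] else FC.UTR3_SNP
    if pos in sets["donor"]:
        return FC.SPLICE_DONOR
    if pos in sets["acceptor"]:
        return FC.SPLICE_ACCEPTOR
    return FC.INTRONIC_INDEL if is_indel else FC.INTRONIC_SNP


def oracle_classify(
    v: VariantCall, models: list[GeneModel], reference
) -> tuple[Optional[GeneModel], FC]:
    """Linear-scan classification collapsed by the stated severity order."""
    entries = [
        (m, oracle_category_in_model(v, m, reference))
        for m in models
        if m.chrom == v.chrom and m.tx_start <= v.pos < m.tx_end
    ]
    if not entries:
        return (
            None,
            FC.INTERGENIC_INDEL if v.var_type is VarType.INDEL else FC.INTERGENIC_SNP,
        )
    return min(entries, key=lambda e: (_ORACLE_RANK[e[1]], e[0].accession))


def oracle_recessive(annotated, threshold: float):
    """Exhaustive per-(sample, gene) application of the three criteria."""
    from varannot.models import InheritanceMode, Zygosity

    keys = sorted(
        {
            (av.sample_variant.sample_id or "", av.record.gene_name)
            for av in annotated
            if av.record.gene_name
        }
    )
    calls = []
    for sample, gene in keys:
        members = [
            av
            for av in annotated
            if (av.sample_variant.sample_id or "") == sample
            and av.record.gene_name == gene
            and av.record.category is FC.EXONIC_REPLACEMENT
            and av.sample_variant.zygosity is not Zygosity.UNKNOWN
            and not av.record.dbsnp_id
            and av.record.phastcons is not None
            and av.record.phastcons > threshold
        ]
        n_hom = sum(1 for av in members if av.sample_variant.zygosity is Zygosity.HOM)
        n_het = sum(1 for av in members if av.sample_variant.zygosity is Zygosity.HET)
        if n_hom >= 1:
            calls.append((sample, gene, InheritanceMode.HOMOZYGOUS))
        if n_het >= 2:
            calls.append((sample, gene, InheritanceMode.COMPOUND_HET))
    return sorted(calls, key=lambda c: (c[0], c[1], c[2].value))
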