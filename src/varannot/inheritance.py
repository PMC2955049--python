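"""Per-sample detection of recessive and compound-heterozygous candidate loci.

A locus (gene) in a sample is called when three criteria all hold:

1. the gene carries at least one homozygous replacement variant
   (homozygous mode) or at least two heterozygous replacement variants
   (compound-heterozygote mode) in that sample;
2. none of the supporting variant positions is present in the
   known-variant catalog;
3. every supporting variant's conservation score is strictly above a
   user-defined threshold (a missing score fails the criterion — absent
   evidence does not pass a conservation filter).

The locus key is the gene name, not the transcript accession, so a
compound heterozygote whose two alleles hit different transcripts of one
gene still pairs.  No phasing is attempted; the two heterozygous alleles
are not verified to lie in trans.
"""
from __future__ import annotations

from dataclasses import dataclass

from .models import (
    AnnotatedVariant,
    FunctionalCategory,
    InheritanceMode,
    RecessiveLocusCall,
    Zygosity,
)


@dataclass(frozen=True)
class RecessiveConfig:
    """Threshold on the conservation score of supporting variants.

    The default of 0.0 filters nothing (scores are strictly positive in
    practice only at conserved bases; a variant scored exactly 0.0 is
    excluded because the comparison is strict).
    """

    phastcons_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phastcons_threshold <= 1.0:
            raise ValueError("phastcons_threshold must lie in [0, 1]")


def _is_candidate(av: AnnotatedVariant, cfg: RecessiveConfig, log=None) -> bool:
    rec = av.record
    if rec.category is not FunctionalCategory.EXONIC_REPLACEMENT:
        return False
    if av.sample_variant.zygosity is Zygosity.UNKNOWN:
        if log is not None:
            log.warn(
                f"variant {rec.chrom}:{rec.position} excluded from recessive "
                f"candidacy: unknown zygosity"
            )
        return False
    if rec.dbsnp_id:
        return False  # position previously reported, allele-matched or not
    if rec.phastcons is None or rec.phastcons <= cfg.phastcons_threshold:
        return False
    return True


def detect_recessive_loci(
    annotated: list[AnnotatedVariant],
    cfg: RecessiveConfig | None = None,
    log=None,
) -> list[RecessiveLocusCall]:
    """Apply the three recessive/compound-het criteria per sample and gene.

    A gene may yield both modes in one sample (a homozygous variant plus
    two heterozygous ones).  Output is sorted by (sample, gene, mode).
    """
    cfg = cfg or RecessiveConfig()
    groups: dict[tuple[str, str], list[AnnotatedVariant]] = {}
    for av in annotated:
        if not _is_candidate(av, cfg, log=log):
            continue
        sample = av.sample_variant.sample_id or ""
        gene = av.record.gene_name
        if not gene:
            continue
        groups.setdefault((sample, gene), []).append(av)

    calls: list[RecessiveLocusCall] = []
    for (sample, gene), avs in groups.items():
        homs = [av.record for av in avs if av.sample_variant.zygosity is Zygosity.HOM]
        hets = [av.record for av in avs if av.sample_variant.zygosity is Zygosity.HET]
        if homs:
            calls.append(
                RecessiveLocusCall(sample, gene, InheritanceMode.HOMOZYGOUS, tuple(homs))
            )
        if len(hets) >= 2:
            calls.append(
                RecessiveLocusCall(sample, gene, InheritanceMode.COMPOUND_HET, tuple(hets))
            )
    calls.sort(key=lambda c: (c.sample_id, c.gene_name, c.mode.value))
    return calls


SUMMARY_HEADER = ["sample_id", "gene_name", "mode", "n_supporting", "variant_positions"]


def summarize_recessive(calls: list[RecessiveLocusCall]) -> list[list[str]]:
    """One summary row per call: sample, gene, mode, count, 1-based positions."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.sample_id, c.gene_name, c.mode.value)):
        positions = ";".join(str(r.position) for r in c.supporting_variants)
        rows.append([c.sample_id, c.gene_name, c.mode.value, str(len(c.supporting_variants)), positions])
    return rows


def write_recessive_summary(calls: list[RecessiveLocusCall], stream) -> None:
    stream.write("\t".join(SUMMARY_HEADER) + "\n")
    for row in summarize_recessive(calls):
        stream.write("\t".join(row) + "\n")
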