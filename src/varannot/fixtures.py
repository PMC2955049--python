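"""Self-contained synthetic datasets with planted ground truth.

The generator builds a toy chromosome carrying multi-exon genes on both
strands with structurally valid coding sequences (length a multiple of 3,
initiator codon, terminal stop, no internal stop, consistent exon frames),
then plants variants hitting every functional category, a known-variant
table covering a subset of them (including '-'-strand records whose
alleles need complementing), a conservation track with controlled scores,
and a small cohort engineered to contain recessive and compound-
heterozygote positives alongside near-miss negatives.

Each planted variant's expected annotation is recorded *during*
generation, from the designed gene structure — not by running the
annotation code — so the truth table is an independent target for
end-to-end tests.  Chromosomes are kept short (default 10 kb) so
exhaustive per-base oracles stay cheap.
"""
from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .annotation_db import expected_exon_frames, revcomp
from .models import (
    CodonChange,
    FunctionalCategory,
    GeneModel,
    InheritanceMode,
    VarAnnotError,
    VarType,
    WarningCode,
    Zygosity,
    iupac_code_for,
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


class FixtureError(VarAnnotError):
    """Requested fixture parameters cannot be satisfied."""


@dataclass(frozen=True)
class TruthRecord:
    """Expected annotation of one planted variant."""

    sample_id: Optional[str]
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str  # as encoded in the variant list (IUPAC for hets)
    var_type: VarType
    zygosity: Zygosity
    category: FunctionalCategory
    aa: Optional[CodonChange]
    rsid: str
    allele_mismatch: bool
    score: Optional[float]
    gene_name: str


@dataclass
class FixtureParams:
    chrom: str = "chrT"
    chrom_length: int = 10_000
    n_genes: int = 4
    # planted variants per functional category
    category_counts: dict[FunctionalCategory, int] = field(
        default_factory=lambda: {c: 2 for c in FunctionalCategory}
    )
    with_cohort: bool = True
    rs_every: int = 2  # every Nth planted variant gets a catalog record
    recessive_threshold: float = 0.5

    def check(self) -> None:
        if self.chrom_length < 1000:
            raise FixtureError("chromosome too short for gene placement")
        if any(n < 0 for n in self.category_counts.values()):
            raise FixtureError("category counts must be non-negative")
        genic = [
            c for c in FunctionalCategory
            if c not in (FunctionalCategory.INTERGENIC_SNP, FunctionalCategory.INTERGENIC_INDEL)
        ]
        if self.n_genes == 0 and any(self.category_counts.get(c, 0) > 0 for c in genic):
            raise FixtureError("genic variants requested but zero genes")
        if self.with_cohort and self.n_genes < 2:
            raise FixtureError("cohort scenarios need at least two genes")


@dataclass
class _Gene:
    """Construction-time bookkeeping for one designed gene."""

    model: GeneModel
    strand: str
    gstart: int
    length: int  # genomic span length
    utr5_len: int
    cds_len: int
    codons: list[str]
    m_to_t: list[int]  # mRNA offset -> gene-local transcript-with-introns offset
    intron_t: list[tuple[int, int]]  # intron intervals in gene-local t coords

    def g(self, t: int) -> int:
        """Gene-local transcript-orientation offset -> genomic position."""
        if self.strand == "+":
            return self.gstart + t
        return self.gstart + self.length - 1 - t

    def g_of_m(self, m: int) -> int:
        return self.g(self.m_to_t[m])

    def coding_gpos(self, ci: int) -> int:
        """Genomic position of CDS offset ``ci``."""
        return self.g_of_m(self.utr5_len + ci)


@dataclass
class FixtureBundle:
    """Generated input texts plus the planted truth."""

    params: FixtureParams
    reference_fasta: str
    gene_table: str
    known_table: str
    wiggle: str
    variant_list: str  # list-of-variants format (no sample column)
    cohort_list: str  # list-of-variants with leading sample ids
    truth: list[TruthRecord]
    recessive_truth: list[tuple[str, str, InheritanceMode]]
    reference: dict[str, str]
    models: list[GeneModel]


def _make_gene(rng: random.Random, chrom: str, gstart: int, strand: str, idx: int) -> tuple[_Gene, str]:
    n_exons = rng.randint(2, 4)
    utr5_len = rng.randint(10, 30)
    n_codons = rng.randint(30, 80)
    cds_len = 3 * n_codons

    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(_BASES) for _ in range(3))
        if codon in _STOPS:
            continue
        if len(codons) == 1 and codon == "ATG":
            continue  # keep codon 2 distinct from the initiator
        codons.append(codon)
    codons.append(rng.choice(_STOPS))

    utr5 = "".join(rng.choice(_BASES) for _ in range(utr5_len))
    # the 3' UTR begins with an in-frame stop so CDS-extension corruptions
    # produce a clean internal-stop signature
    utr3 = "TAA" + "".join(rng.choice(_BASES) for _ in range(rng.randint(10, 30)))
    mrna = utr5 + "".join(codons) + utr3

    # exon split points sit in the CDS interior, leaving >=9 coding bases in
    # the terminal coding exons and whole UTRs inside terminal exons
    lo, hi = utr5_len + 9, utr5_len + cds_len - 9
    splits: list[int] = []
    attempts = 0
    while len(splits) < n_exons - 1:
        attempts += 1
        if attempts > 200:
            raise FixtureError("could not place exon splits")
        p = rng.randint(lo, hi)
        if all(abs(p - q) >= 12 for q in splits):
            splits.append(p)
    splits.sort()
    bounds = [0, *splits, len(mrna)]
    exon_m = [(bounds[i], bounds[i + 1]) for i in range(n_exons)]

    # interleave introns, tracking the mRNA -> gene-local offset map
    m_to_t: list[int] = [0] * len(mrna)
    intron_t: list[tuple[int, int]] = []
    t = 0
    pieces: list[str] = []
    for i, (ma, mb) in enumerate(exon_m):
        for m in range(ma, mb):
            m_to_t[m] = t + (m - ma)
        pieces.append(mrna[ma:mb])
        t += mb - ma
        if i < n_exons - 1:
            ilen = rng.randint(30, 80)
            intron = "".join(rng.choice(_BASES) for _ in range(ilen))
            intron_t.append((t, t + ilen))
            pieces.append(intron)
            t += ilen
    local = "".join(pieces)
    length = len(local)
    genomic_seq = local if strand == "+" else revcomp(local)

    def g_interval(ta: int, tb: int) -> tuple[int, int]:
        if strand == "+":
            return (gstart + ta, gstart + tb)
        return (gstart + length - tb, gstart + length - ta)

    exon_t = []
    t = 0
    for i, (ma, mb) in enumerate(exon_m):
        exon_t.append((t, t + (mb - ma)))
        t += mb - ma
        if i < n_exons - 1:
            t += intron_t[i][1] - intron_t[i][0]
    exons = sorted(g_interval(ta, tb) for ta, tb in exon_t)

    cds_g = sorted(
        (g_interval(m_to_t[utr5_len], m_to_t[utr5_len] + 1)[0],
         g_interval(m_to_t[utr5_len + cds_len - 1], m_to_t[utr5_len + cds_len - 1] + 1)[0])
    )
    model = GeneModel(
        accession=f"NM_{1000 + idx}",
        gene_name=f"GENE{idx + 1}",
        chrom=chrom,
        strand=strand,
        tx_start=gstart,
        tx_end=gstart + length,
        cds_start=cds_g[0],
        cds_end=cds_g[1] + 1,
        exons=tuple(exons),
        exon_frames=(),
    )
    model = dataclasses.replace(model, exon_frames=expected_exon_frames(model))
    model.check()
    gene = _Gene(
        model=model, strand=strand, gstart=gstart, length=length,
        utr5_len=utr5_len, cds_len=cds_len, codons=codons,
        m_to_t=m_to_t, intron_t=intron_t,
    )
    return gene, genomic_seq


@dataclass
class _Plant:
    """A planted variant plus its designed truth, pre-catalog/score."""

    sample_id: Optional[str]
    pos: int
    ref: str
    alt: str  # encoded allele (IUPAC for het SNPs)
    alt_resolved: str  # plain non-reference base for SNPs
    var_type: VarType
    zygosity: Zygosity
    category: FunctionalCategory
    aa: Optional[CodonChange]
    gene_name: str
    rsid: str = ""
    allele_mismatch: bool = False
    score: Optional[float] = None


class _Planter:
    def __init__(self, rng: random.Random, genome: str, genes: list[_Gene], chrom: str):
        self.rng = rng
        self.genome = genome
        self.genes = genes
        self.chrom = chrom
        self.used: set[int] = set()

    def _claim(self, pos: int) -> bool:
        if pos in self.used:
            return False
        self.used.add(pos)
        return True

    def _pick(self, pool: list[int]) -> int:
        pool = [p for p in pool if p not in self.used]
        if not pool:
            raise FixtureError("variant position pool exhausted for a category")
        pos = self.rng.choice(pool)
        self.used.add(pos)
        return pos

    def _snp(self, pos: int, alt: str, het: bool, category: FunctionalCategory,
             aa: Optional[CodonChange], gene_name: str, sample: Optional[str] = None) -> _Plant:
        ref = self.genome[pos]
        encoded = iupac_code_for(ref, alt) if het else alt
        return _Plant(
            sample_id=sample, pos=pos, ref=ref, alt=encoded, alt_resolved=alt,
            var_type=VarType.SNP, zygosity=Zygosity.HET if het else Zygosity.HOM,
            category=category, aa=aa, gene_name=gene_name,
        )

    def _deletion(self, pos: int, category: FunctionalCategory, gene_name: str) -> _Plant:
        ref = self.genome[pos]
        return _Plant(
            sample_id=None, pos=pos, ref=ref, alt="-", alt_resolved="-",
            var_type=VarType.INDEL, zygosity=Zygosity.UNKNOWN,
            category=category, aa=None, gene_name=gene_name,
        )

    def coding_snp(self, gene: _Gene, silent: bool, het: bool,
                   sample: Optional[str] = None) -> _Plant:
        rng = self.rng
        for _ in range(500):
            ci = rng.randrange(gene.cds_len)
            gpos = gene.coding_gpos(ci)
            if gpos in self.used:
                continue
            codon_idx, within = divmod(ci, 3)
            codon = gene.codons[codon_idx]
            ref_aa = _translate(codon)
            choices = []
            for base in _BASES:
                if base == codon[within]:
                    continue
                alt_codon = codon[:within] + base + codon[within + 1:]
                same = _translate(alt_codon) == ref_aa
                if same == silent:
                    choices.append((base, _translate(alt_codon)))
            if not choices:
                continue
            t_alt, alt_aa = rng.choice(choices)
            g_alt = t_alt if gene.strand == "+" else revcomp(t_alt)
            self.used.add(gpos)
            category = (
                FunctionalCategory.EXONIC_SILENT if silent
                else FunctionalCategory.EXONIC_REPLACEMENT
            )
            return self._snp(
                gpos, g_alt, het, category,
                CodonChange(ref_aa, codon_idx + 1, alt_aa),
                gene.model.gene_name, sample,
            )
        raise FixtureError("could not place a coding SNP")

    def plain_snp(self, pool: list[int], category: FunctionalCategory,
                  gene_name: str, het: bool) -> _Plant:
        pos = self._pick(pool)
        ref = self.genome[pos]
        alt = self.rng.choice([b for b in _BASES if b != ref])
        return self._snp(pos, alt, het, category, None, gene_name)

    def deletion(self, pool: list[int], category: FunctionalCategory, gene_name: str) -> _Plant:
        return self._deletion(self._pick(pool), category, gene_name)


def _position_pools(gene: _Gene) -> dict[str, list[int]]:
    """Genomic position pools per structural region of one gene."""
    utr5 = [gene.g_of_m(m) for m in range(gene.utr5_len)]
    utr3_start = gene.utr5_len + gene.cds_len
    mrna_len = len(gene.m_to_t)
    utr3 = [gene.g_of_m(m) for m in range(utr3_start, mrna_len)]
    donors: list[int] = []
    acceptors: list[int] = []
    intron_interior: list[int] = []
    for ia, ib in gene.intron_t:
        donors.extend(gene.g(t) for t in (ia, ia + 1))
        acceptors.extend(gene.g(t) for t in (ib - 2, ib - 1))
        intron_interior.extend(gene.g(t) for t in range(ia + 2, ib - 2))
    return {
        "utr5": utr5,
        "utr3": utr3,
        "donor": donors,
        "acceptor": acceptors,
        "intron": intron_interior,
    }


def _wiggle_text(chrom: str, scores: dict[int, float], rng: random.Random) -> str:
    """Serialize scores exercising both fixedStep and variableStep dialects."""
    lines: list[str] = []
    positions = sorted(scores)
    runs: list[list[int]] = []
    for pos in positions:
        if runs and pos == runs[-1][-1] + 1:
            runs[-1].append(pos)
        else:
            runs.append([pos])
    scattered: list[int] = []
    for run in runs:
        if len(run) >= 5:
            lines.append(f"fixedStep chrom={chrom} start={run[0] + 1} step=1")
            lines.extend(repr(scores[p]) for p in run)
        else:
            scattered.extend(run)
    if scattered:
        lines.append(f"variableStep chrom={chrom}")
        lines.extend(f"{p + 1} {scores[p]!r}" for p in scattered)
    return "\n".join(lines) + ("\n" if lines else "")


def generate_fixture(seed: int, params: Optional[FixtureParams] = None) -> FixtureBundle:
    """Build a complete, deterministic fixture bundle for one seed."""
    params = params or FixtureParams()
    params.check()
    rng = random.Random(seed)
    chrom = params.chrom

    genome = list(rng.choice(_BASES) for _ in range(params.chrom_length))
    genes: list[_Gene] = []
    cursor = 300
    for i in range(params.n_genes):
        gstart = cursor + rng.randint(0, 100)
        strand = "+" if i % 2 == 0 else "-"
        gene, seq = _make_gene(rng, chrom, gstart, strand, i)
        if gene.model.tx_end > params.chrom_length - 300:
            raise FixtureError("chromosome too short for the requested gene count")
        genome[gstart: gstart + gene.length] = seq
        genes.append(gene)
        cursor = gstart + gene.length + rng.randint(250, 400)
    genome_str = "".join(genome)

    # intergenic pool: >=50 bp clear of every transcript
    blocked: set[int] = set()
    for gene in genes:
        blocked.update(range(gene.model.tx_start - 50, gene.model.tx_end + 50))
    intergenic_pool = [
        p for p in range(50, params.chrom_length - 50) if p not in blocked
    ]

    planter = _Planter(rng, genome_str, genes, chrom)
    plants: list[_Plant] = []

    def gene_cycle():
        i = 0
        while True:
            yield genes[i % len(genes)]
            i += 1

    cyc = gene_cycle()
    counts = params.category_counts
    for _ in range(counts.get(FunctionalCategory.EXONIC_REPLACEMENT, 0)):
        plants.append(planter.coding_snp(next(cyc), silent=False, het=rng.random() < 0.5))
    for _ in range(counts.get(FunctionalCategory.EXONIC_SILENT, 0)):
        plants.append(planter.coding_snp(next(cyc), silent=True, het=rng.random() < 0.5))
    simple = [
        (FunctionalCategory.SPLICE_DONOR, "donor"),
        (FunctionalCategory.SPLICE_ACCEPTOR, "acceptor"),
        (FunctionalCategory.UTR5_SNP, "utr5"),
        (FunctionalCategory.UTR3_SNP, "utr3"),
        (FunctionalCategory.INTRONIC_SNP, "intron"),
    ]
    for category, pool_name in simple:
        for _ in range(counts.get(category, 0)):
            gene = next(cyc)
            pools = _position_pools(gene)
            plants.append(
                planter.plain_snp(pools[pool_name], category, gene.model.gene_name,
                                  het=rng.random() < 0.5)
            )
    for _ in range(counts.get(FunctionalCategory.INTERGENIC_SNP, 0)):
        plants.append(planter.plain_snp(intergenic_pool, FunctionalCategory.INTERGENIC_SNP, "", het=rng.random() < 0.5))
    indel_specs = [
        (FunctionalCategory.EXONIC_INDEL, "cds"),
        (FunctionalCategory.UTR_INDEL, "utr3"),
        (FunctionalCategory.INTRONIC_INDEL, "intron"),
    ]
    for category, pool_name in indel_specs:
        for _ in range(counts.get(category, 0)):
            gene = next(cyc)
            if pool_name == "cds":
                pool = [gene.coding_gpos(ci) for ci in range(gene.cds_len)]
            else:
                pool = _position_pools(gene)[pool_name]
            plants.append(planter.deletion(pool, category, gene.model.gene_name))
    for _ in range(counts.get(FunctionalCategory.INTERGENIC_INDEL, 0)):
        plants.append(planter.deletion(intergenic_pool, FunctionalCategory.INTERGENIC_INDEL, ""))

    # known-variant catalog over a subset of the planted variants
    known_rows: list[str] = []
    rs_serial = 1000
    mismatch_done = False
    for i, plant in enumerate(plants):
        if params.rs_every and i % params.rs_every == 0:
            rs_serial += 1
            strand = rng.choice("+-")
            alleles = {plant.ref, plant.alt_resolved}
            if strand == "-":
                alleles = {"-" if a == "-" else revcomp(a) for a in alleles}
            het = round(rng.uniform(0.01, 0.5), 3)
            known_rows.append("\t".join([
                f"rs{rs_serial}", chrom, str(plant.pos), strand,
                "/".join(sorted(alleles)), repr(het),
            ]))
            plant.rsid = f"rs{rs_serial}"
        elif not mismatch_done and plant.var_type is VarType.SNP:
            # one position-level hit whose alleles do not cover the call
            rs_serial += 1
            known_rows.append("\t".join([
                f"rs{rs_serial}", chrom, str(plant.pos), "+",
                plant.ref, repr(round(rng.uniform(0.01, 0.5), 3)),
            ]))
            plant.rsid = f"rs{rs_serial}"
            plant.allele_mismatch = True
            mismatch_done = True
    # background catalog records at unused positions
    for _ in range(5):
        pos = planter._pick(intergenic_pool)
        ref = genome_str[pos]
        alt = rng.choice([b for b in _BASES if b != ref])
        rs_serial += 1
        known_rows.append("\t".join([
            f"rs{rs_serial}", chrom, str(pos), "+",
            "/".join(sorted({ref, alt})), repr(round(rng.uniform(0.01, 0.5), 3)),
        ]))

    # cohort engineered around the recessive criteria
    cohort_plants: list[_Plant] = []
    recessive_truth: list[tuple[str, str, InheritanceMode]] = []
    if params.with_cohort:
        gene_a, gene_b = genes[0], genes[1]
        thr = params.recessive_threshold
        hi = round(min(1.0, thr + 0.35), 3)
        hi2 = round(min(1.0, thr + 0.25), 3)
        lo = round(max(0.0, thr - 0.3), 3)

        def cohort_snp(gene: _Gene, sample: str, het: bool, score: float,
                       silent: bool = False, rsid: str = "") -> _Plant:
            plant = planter.coding_snp(gene, silent=silent, het=het, sample=sample)
            plant.score = score
            if rsid:
                plant.rsid = rsid
                alleles = "/".join(sorted({plant.ref, plant.alt_resolved}))
                known_rows.append("\t".join([
                    rsid, chrom, str(plant.pos), "+", alleles,
                    repr(round(rng.uniform(0.01, 0.5), 3)),
                ]))
            return plant

        # positive: compound het in GENE1 for S1
        cohort_plants += [
            cohort_snp(gene_a, "S1", het=True, score=hi),
            cohort_snp(gene_a, "S1", het=True, score=hi2),
        ]
        recessive_truth.append(("S1", gene_a.model.gene_name, InheritanceMode.COMPOUND_HET))
        # positive: homozygous in GENE2 for S1
        cohort_plants.append(cohort_snp(gene_b, "S1", het=False, score=hi))
        recessive_truth.append(("S1", gene_b.model.gene_name, InheritanceMode.HOMOZYGOUS))
        # negative: a single het only (criterion 1 unmet)
        cohort_plants.append(cohort_snp(gene_a, "S2", het=True, score=hi))
        # negative: pair with one catalogued position (criterion 2 veto)
        rs_serial += 1
        cohort_plants += [
            cohort_snp(gene_b, "S2", het=True, score=hi),
            cohort_snp(gene_b, "S2", het=True, score=hi2, rsid=f"rs{rs_serial}"),
        ]
        # negative: pair with one weakly conserved position (criterion 3)
        cohort_plants += [
            cohort_snp(gene_a, "S3", het=True, score=hi),
            cohort_snp(gene_a, "S3", het=True, score=lo),
        ]
        # negative: one het replacement plus one silent het
        cohort_plants += [
            cohort_snp(gene_b, "S3", het=True, score=hi),
            cohort_snp(gene_b, "S3", het=True, score=hi2, silent=True),
        ]

    # conservation track: background runs plus controlled per-variant scores;
    # intergenic plants stay uncovered so a missing score is exercised
    scores: dict[int, float] = {}
    for _ in range(6):
        start = rng.randrange(0, params.chrom_length - 40)
        for p in range(start, start + rng.randint(8, 30)):
            scores[p] = round(rng.random(), 3)
    for plant in plants:
        if plant.category in (FunctionalCategory.INTERGENIC_SNP, FunctionalCategory.INTERGENIC_INDEL):
            scores.pop(plant.pos, None)
            plant.score = None
        else:
            if plant.score is None:
                plant.score = round(rng.random(), 3)
            scores[plant.pos] = plant.score
    for plant in cohort_plants:
        scores[plant.pos] = plant.score

    def list_row(plant: _Plant, with_sample: bool) -> str:
        fields = [
            chrom, str(plant.pos + 1), str(plant.pos % 97 + 1),
            plant.ref, plant.alt, plant.var_type.value,
        ]
        if with_sample:
            fields.insert(0, plant.sample_id or "")
        return "\t".join(fields)

    truth = [
        TruthRecord(
            sample_id=p.sample_id, chrom=chrom, pos=p.pos, ref_allele=p.ref,
            alt_allele=p.alt, var_type=p.var_type, zygosity=p.zygosity,
            category=p.category, aa=p.aa, rsid=p.rsid,
            allele_mismatch=p.allele_mismatch, score=p.score, gene_name=p.gene_name,
        )
        for p in plants + cohort_plants
    ]

    from .annotation_db import serialize_gene_table

    models = [g.model for g in genes]
    return FixtureBundle(
        params=params,
        reference_fasta=f">{chrom}\n" + "\n".join(
            genome_str[i: i + 70] for i in range(0, len(genome_str), 70)
        ) + "\n",
        gene_table=serialize_gene_table(models),
        known_table="\n".join(known_rows) + ("\n" if known_rows else ""),
        wiggle=_wiggle_text(chrom, scores, rng),
        variant_list="\n".join(list_row(p, False) for p in plants) + ("\n" if plants else ""),
        cohort_list="\n".join(list_row(p, True) for p in cohort_plants)
        + ("\n" if cohort_plants else ""),
        truth=truth,
        recessive_truth=recessive_truth,
        reference={chrom: genome_str},
        models=models,
    )


def corrupt_gene_model(model: GeneModel, code: WarningCode) -> GeneModel:
    """Minimally edit a generator-built clean model to trigger one warning.

    The edits rely on structural guarantees of :func:`generate_fixture`:
    whole UTRs (the 3' UTR starting with an in-frame TAA) inside the
    terminal exons, at least 9 coding bases in each terminal coding exon,
    and a second codon that is not ATG.
    """
    plus = model.strand == "+"

    def shift_3prime(k: int) -> GeneModel:
        if plus:
            return dataclasses.replace(model, cds_end=model.cds_end + k)
        return dataclasses.replace(model, cds_start=model.cds_start - k)

    def shift_5prime(k: int) -> GeneModel:
        if plus:
            return dataclasses.replace(model, cds_start=model.cds_start + k)
        return dataclasses.replace(model, cds_end=model.cds_end - k)

    if code is WarningCode.CDS_NOT_MULTIPLE_OF_3:
        return shift_3prime(1)
    if code is WarningCode.INTERNAL_STOP:
        return shift_3prime(3)  # absorbs the planted TAA after the stop
    if code is WarningCode.MISSING_STOP:
        return shift_3prime(-3)
    if code is WarningCode.MISSING_START:
        return shift_5prime(3)
    if code is WarningCode.FRAME_MISMATCH:
        frames = list(model.exon_frames)
        for i, f in enumerate(frames):
            if f != -1:
                frames[i] = (f + 1) % 3
                break
        return dataclasses.replace(model, exon_frames=tuple(frames))
    if code is WarningCode.OUT_OF_BOUNDS:
        return dataclasses.replace(model, tx_end=model.tx_end + 10**9)
    raise VarAnnotError(f"unknown warning code {code!r}")
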