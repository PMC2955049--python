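"""Functional classification, codon consequences and record assembly."""
import dataclasses
import random

import pytest

from varannot import (
    FunctionalCategory as FC,
    GeneModel,
    SampleVariant,
    VariantCall,
    VarType,
    Zygosity,
    annotate_variant,
    build_gene_index,
    classify_site,
    compute_amino_acid_change,
    corrupt_gene_model,
)
from varannot.annotation_db import revcomp
from varannot.functional import AnnotationDatabase
from varannot.models import WarningCode

from oracles import oracle_classify, oracle_codon_change


def snp(chrom, pos, ref, alt):
    return VariantCall(chrom, pos, ref, alt, VarType.SNP)


@pytest.fixture(scope="module")
def toy_db(toy_model, toy_reference):
    return AnnotationDatabase.build(toy_reference, [toy_model])


class TestClassifySite:
    def test_no_overlap_is_intergenic(self, toy_db, toy_reference):
        (entry,) = classify_site(snp("chrM", 2, "A", "T"), toy_db.gene_index, toy_reference)
        assert entry == (None, FC.INTERGENIC_SNP)

    def test_first_intron_base_after_exon_is_splice_donor(self, toy_db, toy_model, toy_reference):
        # exon 1 ends at 25; 25 and 26 are the canonical GT dinucleotide
        for pos in (25, 26):
            (entry,) = classify_site(
                snp("chrM", pos, toy_reference["chrM"][pos], "C"),
                toy_db.gene_index, toy_reference,
            )
            assert entry == (toy_model, FC.SPLICE_DONOR)

    def test_last_two_intron_bases_are_splice_acceptor(self, toy_db, toy_model, toy_reference):
        for pos in (28, 29):
            (entry,) = classify_site(
                snp("chrM", pos, toy_reference["chrM"][pos], "C"),
                toy_db.gene_index, toy_reference,
            )
            assert entry == (toy_model, FC.SPLICE_ACCEPTOR)

    def test_intron_interior_is_intronic(self, toy_db, toy_reference):
        (entry,) = classify_site(snp("chrM", 27, "A", "C"), toy_db.gene_index, toy_reference)
        assert entry[1] is FC.INTRONIC_SNP

    def test_exonic_position_before_cds_on_plus_strand_is_utr5(self, toy_db, toy_reference):
        (entry,) = classify_site(snp("chrM", 7, "C", "G"), toy_db.gene_index, toy_reference)
        assert entry[1] is FC.UTR5_SNP

    def test_exonic_position_after_cds_on_plus_strand_is_utr3(self, toy_db, toy_reference):
        (entry,) = classify_site(snp("chrM", 40, "T", "G"), toy_db.gene_index, toy_reference)
        assert entry[1] is FC.UTR3_SNP

    def test_coding_deletion_is_exonic_indel(self, toy_db, toy_reference):
        v = VariantCall("chrM", 14, "T", "-", VarType.INDEL)
        (entry,) = classify_site(v, toy_db.gene_index, toy_reference)
        assert entry[1] is FC.EXONIC_INDEL

    def test_chromosome_without_models_is_intergenic_with_log(self, toy_db, toy_reference):
        from varannot.writers import RunLog
        log = RunLog()
        ref = dict(toy_reference, chrQ="ACGTACGT")
        (entry,) = classify_site(snp("chrQ", 3, "T", "C"), toy_db.gene_index, ref, log=log)
        assert entry == (None, FC.INTERGENIC_SNP)
        assert log.count("WARN") == 1


class TestCodonChange:
    def test_missense_in_second_codon(self, toy_model, toy_reference):
        # codon 2 is ATT (Ile); middle-base T>A gives AAT (Asn)
        change = compute_amino_acid_change(snp("chrM", 14, "T", "A"), toy_model, toy_reference)
        assert (change.ref_aa, change.aa_pos, change.alt_aa) == ("I", 2, "N")

    def test_silent_third_base_of_codon(self, toy_model, toy_reference):
        # codon 3 is GGA (Gly); third-base A>G gives GGG (Gly)
        change = compute_amino_acid_change(snp("chrM", 18, "A", "G"), toy_model, toy_reference)
        assert (change.ref_aa, change.aa_pos, change.alt_aa) == ("G", 3, "G")

    def test_het_iupac_alt_resolved_before_translation(self, toy_model, toy_reference):
        # W = {A,T} at ref T resolves to A: same consequence as the plain call
        change = compute_amino_acid_change(snp("chrM", 14, "T", "W"), toy_model, toy_reference)
        assert (change.ref_aa, change.aa_pos, change.alt_aa) == ("I", 2, "N")

    def test_change_spanning_spliced_exon_boundary_codon(self, toy_model, toy_reference):
        # codon 6 (GAA) is entirely in exon 2 after splicing out the intron
        change = compute_amino_acid_change(snp("chrM", 31, "A", "T"), toy_model, toy_reference)
        assert (change.ref_aa, change.aa_pos, change.alt_aa) == ("E", 6, "V")

    def test_trailing_partial_codon_of_broken_model_is_undetermined(
        self, toy_model, toy_reference
    ):
        broken = corrupt_gene_model(toy_model, WarningCode.CDS_NOT_MULTIPLE_OF_3)
        # the extension added genomic base 36 to the CDS as a trailing 22nd base
        assert compute_amino_acid_change(snp("chrM", 36, "T", "A"), broken, toy_reference) is None

    def test_random_coding_snps_match_full_cds_translation_oracle(self, bundle, db):
        rng = random.Random(11)
        ref = bundle.reference
        for _ in range(200):
            model = rng.choice(bundle.models)
            coding = [p for s, e in model.coding_intervals() for p in range(s, e)]
            pos = rng.choice(coding)
            ref_base = ref[model.chrom][pos]
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            v = snp(model.chrom, pos, ref_base, alt)
            change = compute_amino_acid_change(v, model, ref)
            assert (change.ref_aa, change.aa_pos, change.alt_aa) == oracle_codon_change(v, model, ref)


def mirror(model: GeneModel, reference: dict) -> tuple[GeneModel, dict]:
    """Coordinate-mirrored model on the reverse-complemented chromosome."""
    L = len(reference[model.chrom])
    flip = lambda s, e: (L - e, L - s)
    exons = tuple(sorted(flip(s, e) for s, e in model.exons))
    mirrored = dataclasses.replace(
        model,
        strand="-" if model.strand == "+" else "+",
        tx_start=L - model.tx_end, tx_end=L - model.tx_start,
        cds_start=L - model.cds_end, cds_end=L - model.cds_start,
        exons=exons,
        exon_frames=tuple(reversed(model.exon_frames)),
    )
    return mirrored, {model.chrom: revcomp(reference[model.chrom])}


class TestStrandSymmetry:
    def test_mirrored_minus_model_gives_identical_consequences(self, bundle):
        """A '+' gene and its mirror on the reverse complement must agree."""
        rng = random.Random(3)
        ref = bundle.reference
        L = len(ref["chrT"])
        for model in bundle.models:
            mirrored, mref = mirror(model, ref)
            index_f = build_gene_index([model])
            index_m = build_gene_index([mirrored])
            coding = [p for s, e in model.coding_intervals() for p in range(s, e)]
            for pos in rng.sample(coding, 40):
                ref_base = ref[model.chrom][pos]
                alt = rng.choice([b for b in "ACGT" if b != ref_base])
                v = snp(model.chrom, pos, ref_base, alt)
                vm = snp(model.chrom, L - 1 - pos, revcomp(ref_base), revcomp(alt))
                (_, cat_f), = classify_site(v, index_f, ref)
                (_, cat_m), = classify_site(vm, index_m, mref)
                assert cat_f == cat_m
                if cat_f in (FC.EXONIC_REPLACEMENT, FC.EXONIC_SILENT):
                    cf = compute_amino_acid_change(v, model, ref)
                    cm = compute_amino_acid_change(vm, mirrored, mref)
                    assert cf == cm


class TestAnnotateVariant:
    def test_intergenic_record_has_empty_gene_and_lookup_fields(self, toy_db):
        record = annotate_variant(SampleVariant(snp("chrM", 2, "A", "T")), toy_db)
        assert record.category is FC.INTERGENIC_SNP
        assert record.position == 3  # reported 1-based
        assert record.gene_name == "" and record.gene_strand == ""
        assert record.refseq_ids == () and record.dbsnp_id == ""
        assert record.ref_aa == "" and record.aa_pos is None
        assert record.phastcons is None

    def test_severity_collapse_keeps_all_accessions(self, toy_model, toy_reference):
        # second transcript overlaps the coding SNP with a UTR exon only
        other = dataclasses.replace(
            toy_model, accession="NM_0002", gene_name="TOY2",
            cds_start=50, cds_end=50, exon_frames=(-1, -1),
        )
        db2 = AnnotationDatabase.build(toy_reference, [toy_model, other])
        record = annotate_variant(SampleVariant(snp("chrM", 14, "T", "A")), db2)
        assert record.category is FC.EXONIC_REPLACEMENT
        assert record.refseq_ids == ("NM_0001", "NM_0002")
        assert record.gene_name == "TOY1"

    def test_collapse_invariant_under_model_order(self, toy_model, toy_reference):
        other = dataclasses.replace(
            toy_model, accession="NM_0002", cds_start=50, cds_end=50,
            exon_frames=(-1, -1),
        )
        sv = SampleVariant(snp("chrM", 14, "T", "A"))
        rec_ab = annotate_variant(sv, AnnotationDatabase.build(toy_reference, [toy_model, other]))
        rec_ba = annotate_variant(sv, AnnotationDatabase.build(toy_reference, [other, toy_model]))
        assert rec_ab == rec_ba

    def test_known_variant_fields_passed_through_as_stored(self, toy_model, toy_reference):
        from varannot import parse_known_variant_table
        known = parse_known_variant_table(["rs55\tchrM\t14\t-\tA/T\t0.25"])
        db2 = AnnotationDatabase.build(toy_reference, [toy_model], known_index=known)
        record = annotate_variant(SampleVariant(snp("chrM", 14, "T", "A")), db2)
        assert (record.dbsnp_id, record.dbsnp_heterozygosity, record.dbsnp_orientation) == (
            "rs55", 0.25, "-",
        )
        assert not record.dbsnp_allele_mismatch

    def test_model_warnings_propagate_to_record(self, toy_model, toy_reference):
        broken = corrupt_gene_model(toy_model, WarningCode.MISSING_STOP)
        db2 = AnnotationDatabase.build(toy_reference, [broken])
        record = annotate_variant(SampleVariant(snp("chrM", 14, "T", "A")), db2)
        assert record.warnings == ("MISSING_STOP",)


class TestPerBaseOracleEquivalence:
    def test_every_position_of_small_chromosome_matches_brute_force(self, small_bundle):
        bundle = small_bundle
        ref = bundle.reference
        seq = ref["chrT"]
        index = build_gene_index(bundle.models)
        from varannot.functional import _collapse
        mismatches = 0
        for pos in range(len(seq)):
            ref_base = seq[pos]
            alt = "A" if ref_base != "A" else "C"
            v = snp("chrT", pos, ref_base, alt)
            got = _collapse(classify_site(v, index, ref))
            expected = oracle_classify(v, bundle.models, ref)
            if got != expected:
                mismatches += 1
        assert mismatches == 0
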