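"""Gene table, known-variant table, conservation track and index behaviour."""
import random

import pytest

from varannot import (
    ParseError,
    VarAnnotError,
    WarningCode,
    build_gene_index,
    corrupt_gene_model,
    parse_conservation_wiggle,
    parse_gene_table,
    parse_known_variant_table,
    query_known,
    serialize_gene_table,
    validate_gene_model,
)
from varannot.models import GeneModel


def _row(accession="NM_1", chrom="chrT", strand="+", tx=(10, 90), cds=(10, 90),
         starts="10,50,", ends="40,90,", n=2, gene="G1", frames="0,0,"):
    return "\t".join([
        accession, chrom, strand, str(tx[0]), str(tx[1]), str(cds[0]), str(cds[1]),
        str(n), starts, ends, gene, frames,
    ])


class TestParseGeneTable:
    def test_exon_lists_reconstructed_from_comma_columns(self):
        (m,) = parse_gene_table([_row()])
        assert m.exons == ((10, 40), (50, 90))
        assert m.exon_frames == (0, 0)
        assert (m.accession, m.gene_name, m.strand) == ("NM_1", "G1", "+")

    def test_empty_stream_gives_empty_list(self):
        assert parse_gene_table([]) == []

    def test_exon_count_mismatch_names_line(self):
        rows = [_row(), _row(accession="NM_2", starts="10,50,70,", n=2)]
        with pytest.raises(ParseError, match="line 2"):
            parse_gene_table(rows)

    @pytest.mark.parametrize("bad", [
        _row() + "\textra",
        _row(tx=("x", 90)),
        _row(cds=(5, 90)),  # cdsStart < txStart
    ])
    def test_malformed_rows_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_gene_table([bad])

    def test_round_trip_is_identity(self, bundle):
        models = parse_gene_table(bundle.gene_table.splitlines())
        again = parse_gene_table(serialize_gene_table(models).splitlines())
        assert again == models


class TestGeneIndex:
    def test_disjoint_query_is_empty(self):
        index = build_gene_index(parse_gene_table([_row()]))
        assert index.query("chrT", 0, 5) == []

    def test_half_open_boundary_overlap(self):
        index = build_gene_index(parse_gene_table([_row()]))
        assert [m.accession for m in index.query("chrT", 89, 91)] == ["NM_1"]
        assert index.query("chrT", 90, 95) == []

    def test_duplicate_model_rejected(self):
        models = parse_gene_table([_row(), _row()])
        with pytest.raises(VarAnnotError, match="duplicate"):
            build_gene_index(models)

    def test_random_queries_match_linear_scan(self):
        rng = random.Random(42)
        models = []
        for i in range(100):
            s = rng.randrange(0, 5000)
            e = s + rng.randrange(10, 400)
            models.append(GeneModel(
                accession=f"NM_{i}", gene_name=f"G{i}", chrom=rng.choice(["chrA", "chrB"]),
                strand="+", tx_start=s, tx_end=e, cds_start=s, cds_end=s,
                exons=((s, e),), exon_frames=(-1,),
            ))
        index = build_gene_index(models)
        for _ in range(1000):
            chrom = rng.choice(["chrA", "chrB", "chrC"])
            qs = rng.randrange(0, 5500)
            qe = qs + rng.randrange(1, 300)
            expected = sorted(
                (m for m in models if m.chrom == chrom and m.tx_start < qe and qs < m.tx_end),
                key=lambda m: (m.tx_start, m.tx_end, m.accession),
            )
            assert index.query(chrom, qs, qe) == expected


class TestValidateGeneModel:
    def test_clean_toy_model_passes(self, toy_model, toy_reference):
        assert validate_gene_model(toy_model, toy_reference) == []

    def test_clean_generated_models_pass(self, bundle):
        for m in bundle.models:
            assert validate_gene_model(m, bundle.reference) == []

    def test_cds_length_not_multiple_of_3_flagged(self, toy_model, toy_reference):
        import dataclasses
        # coding length becomes 15 + 8 = 23
        broken = dataclasses.replace(toy_model, cds_end=38)
        codes = {w.code for w in validate_gene_model(broken, toy_reference)}
        assert WarningCode.CDS_NOT_MULTIPLE_OF_3 in codes

    def test_out_of_bounds_transcript_flagged(self, toy_model, toy_reference):
        import dataclasses
        broken = dataclasses.replace(toy_model, tx_end=10_000)
        codes = [w.code for w in validate_gene_model(broken, toy_reference)]
        assert codes == [WarningCode.OUT_OF_BOUNDS]

    def test_absent_chromosome_is_an_error(self, toy_model):
        with pytest.raises(VarAnnotError, match="absent"):
            validate_gene_model(toy_model, {"chrZ": "ACGT"})

    @pytest.mark.parametrize("code", list(WarningCode))
    def test_each_corruption_triggers_exactly_its_code(self, bundle, code):
        for model in bundle.models:
            corrupted = corrupt_gene_model(model, code)
            got = [w.code for w in validate_gene_model(corrupted, bundle.reference)]
            assert got == [code], (model.accession, code, got)


class TestKnownVariants:
    def test_store_and_retrieve(self):
        index = parse_known_variant_table(["rs100\tchrT\t30\t-\tC/T\t0.25"])
        (rec,) = index.at("chrT", 30)
        assert rec.rsid == "rs100"
        assert rec.alleles == frozenset({"C", "T"})
        assert rec.heterozygosity == 0.25

    def test_unlisted_position_has_no_record(self):
        index = parse_known_variant_table(["rs100\tchrT\t30\t-\tC/T\t0.25"])
        assert index.at("chrT", 31) == []
        assert query_known(index, "chrT", 31, "A", "G") is None

    def test_heterozygosity_outside_unit_interval_rejected(self):
        with pytest.raises(ParseError):
            parse_known_variant_table(["rs1\tchrT\t30\t+\tA/T\t1.5"])

    def test_minus_strand_record_matches_complemented_query(self):
        # record alleles {C,T} on '-'; reference-strand G/A is the complement
        index = parse_known_variant_table(["rs100\tchrT\t30\t-\tC/T\t0.25"])
        match = query_known(index, "chrT", 30, "G", "A")
        assert match is not None and not match.allele_mismatch
        assert match.record.rsid == "rs100"
        assert match.record.strand == "-"  # orientation reported as stored

    def test_empty_index_query_is_none(self):
        index = parse_known_variant_table([])
        assert query_known(index, "chrT", 30, "A", "G") is None

    def test_position_hit_with_foreign_alleles_sets_mismatch_flag(self):
        index = parse_known_variant_table(["rs7\tchrT\t12\t+\tA/G\t0.1"])
        match = query_known(index, "chrT", 12, "A", "T")
        assert match is not None and match.allele_mismatch
        assert match.record.rsid == "rs7"


class TestConservationWiggle:
    def test_fixed_step_one_based_conversion(self):
        track = parse_conservation_wiggle(
            ["fixedStep chrom=chrT start=11 step=1", "0.1", "0.2", "0.3"]
        )
        # declared 1-based start 11 is 0-based 10; the second value sits at 11
        assert track.get("chrT", 10) == 0.1
        assert track.get("chrT", 11) == 0.2
        assert track.get("chrT", 12) == 0.3

    def test_variable_step_one_based_conversion(self):
        track = parse_conservation_wiggle(["variableStep chrom=chrT", "15 0.7"])
        assert track.get("chrT", 14) == 0.7
        assert track.get("chrT", 15) is None

    def test_span_covers_consecutive_bases(self):
        track = parse_conservation_wiggle(
            ["fixedStep chrom=chrT start=1 step=5 span=3", "0.5", "0.6"]
        )
        assert [track.get("chrT", p) for p in range(0, 8)] == [
            0.5, 0.5, 0.5, None, None, 0.6, 0.6, 0.6
        ]

    def test_positions_outside_track_return_missing_not_zero(self):
        track = parse_conservation_wiggle(["fixedStep chrom=chrT start=1", "0.0"])
        assert track.get("chrT", 0) == 0.0
        assert track.get("chrT", 1) is None
        assert track.get("chrX", 0) is None

    @pytest.mark.parametrize("lines", [
        ["wibbleStep chrom=chrT start=1", "0.5"],
        ["fixedStep chrom=chrT start=1", "1.5"],
        ["0.5"],
    ])
    def test_malformed_streams_rejected(self, lines):
        with pytest.raises(ParseError):
            parse_conservation_wiggle(lines)
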