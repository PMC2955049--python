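import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from varannot import GeneModel, generate_fixture
from varannot.fixtures import FixtureParams
from varannot.functional import AnnotationDatabase


# A hand-built '+'-strand two-exon gene on a 60 bp chromosome, used for
# worked examples where every base is known:
#   0-4    upstream            AAAAA
#   5-9    5' UTR (exon 1)     CCCCC
#   10-24  CDS in exon 1       ATG ATT GGA TCT AAA
#   25-29  intron              GTAAG
#   30-35  CDS in exon 2       GAA TAA
#   36-54  3' UTR (exon 2)     T*19
#   55-59  downstream          GGGGG
# Peptide: M I G S K E *
TOY_SEQ = "AAAAA" + "CCCCC" + "ATGATTGGATCTAAA" + "GTAAG" + "GAATAA" + "T" * 19 + "GGGGG"


@pytest.fixture(scope="session")
def toy_reference():
    return {"chrM": TOY_SEQ}


@pytest.fixture(scope="session")
def toy_model():
    return GeneModel(
        accession="NM_0001",
        gene_name="TOY1",
        chrom="chrM",
        strand="+",
        tx_start=5,
        tx_end=55,
        cds_start=10,
        cds_end=36,
        exons=((5, 25), (30, 55)),
        exon_frames=(0, 0),
    )


@pytest.fixture(scope="session")
def bundle():
    """Standard synthetic dataset: 10 kb chromosome, 4 genes, full cohort."""
    return generate_fixture(1)


@pytest.fixture(scope="session")
def db(bundle):
    return AnnotationDatabase.from_texts(
        bundle.reference, bundle.gene_table, bundle.known_table, bundle.wiggle
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Compact dataset for exhaustive per-base scans in unit tests."""
    params = FixtureParams(chrom_length=4000, n_genes=2, with_cohort=True)
    return generate_fixture(7, params)
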