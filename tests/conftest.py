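import pytest

from scedit.calling import FilterThresholds, call_edit_sites
from scedit.io import GeneModel
from scedit.simulate import SimulationConfig, build_toy_dataset

#: small, fast configuration for I/O and plumbing tests
SMALL = dict(
    n_genes=8,
    n_cells={"Ib": 15, "Is": 15, "muscle": 6},
    true_edit_sites=10,
    seed=5,
)

#: study-scale defaults: 100 cells per neuronal subtype, depth mean 40,
#: base-call error 2e-3, 50 planted edits
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def small_dataset():
    return build_toy_dataset(SimulationConfig(**SMALL))


@pytest.fixture(scope="session")
def small_sites(small_dataset):
    return call_edit_sites(
        small_dataset.observations,
        small_dataset.gene_models,
        small_dataset.parental_sets,
        FilterThresholds(min_cells=5),
    )


@pytest.fixture(scope="session")
def default_dataset():
    return build_toy_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_sites(default_dataset):
    return call_edit_sites(
        default_dataset.observations,
        default_dataset.gene_models,
        default_dataset.parental_sets,
    )


@pytest.fixture
def plus_gene():
    """chrom p1: 5'UTR 1-6, CDS 7-18 (ATG AGT TAT TAG), 3'UTR 19-24."""
    return GeneModel(
        gene_id="plus1",
        chrom="p1",
        strand="+",
        utr5=((1, 6),),
        cds=((7, 18),),
        utr3=((19, 24),),
        cds_sequence="ATGAGTTATTAG",
    )


@pytest.fixture
def minus_gene():
    """chrom m1: transcribed right-to-left; 3'UTR 1-6, CDS 7-18, 5'UTR 19-24.

    Sense CDS = ATG AGT TAT TAG, so the plus-strand reference slice 7-18 is
    its reverse complement, CTAATAACTCAT.
    """
    return GeneModel(
        gene_id="minus1",
        chrom="m1",
        strand="-",
        utr5=((19, 24),),
        cds=((7, 18),),
        utr3=((1, 6),),
        cds_sequence="ATGAGTTATTAG",
    )


@pytest.fixture
def toy_reference(plus_gene, minus_gene):
    # p1: utr5 AACCGG | CDS ATGAGTTATTAG | utr3 TTGGCC
    # m1 plus strand: revcomp(utr3+CDS+utr5 sense) laid out left to right
    from Bio.Seq import Seq

    sense_mrna = "AACCGG" + "ATGAGTTATTAG" + "TTGGCC"  # 5'UTR + CDS + 3'UTR
    return {
        "p1": sense_mrna,
        "m1": str(Seq(sense_mrna).reverse_complement()),
    }
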