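import pytest

from m1ascan import pileup, synthetic
from m1ascan.reference_io import GeneModel


@pytest.fixture(scope="session")
def small_dataset():
    """40-gene dataset with default (study-condition) parameters."""
    return synthetic.simulate_dataset(synthetic.SimulationConfig(n_genes=40, seed=1))


@pytest.fixture(scope="session")
def small_observations(small_dataset):
    ds = small_dataset
    return pileup.extract_adenosine_observations(
        ds.pileups, ds.reference.models, ds.reference.genome
    )


@pytest.fixture
def single_exon_plus():
    """Exon 100-400 (+), CDS 150-350 in genomic coordinates."""
    return GeneModel(
        "gA", "chr1", "+", [(100, 400)],
        cds_span=(50, 250), utr5_span=(0, 50), utr3_span=(250, 300),
    )


@pytest.fixture
def single_exon_minus():
    """Same intervals on the minus strand."""
    return GeneModel(
        "gB", "chr1", "-", [(100, 400)],
        cds_span=(50, 250), utr5_span=(0, 50), utr3_span=(250, 300),
    )
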