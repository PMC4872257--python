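import numpy as np
import pytest

from promotif.genome_io import UpstreamRegion
from promotif.synthetic import sample_background_sequences, uniform_background


@pytest.fixture(scope="session")
def flat_background():
    return uniform_background(max_order=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_regions(flat_background):
    """Ten 1 kb promoters from the flat background."""
    return sample_background_sequences(flat_background, 10, 1000, seed=101)


def make_region(seq: str, gene_id: str = "g1", strand: str = "+",
                start: int = 0) -> UpstreamRegion:
    return UpstreamRegion(gene_id, "chr1", strand, start, start + len(seq),
                          seq)


@pytest.fixture
def region_factory():
    return make_region
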