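import numpy as np
import pytest

from numtpipe.genome import GenomeModel, demo_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_model():
    return demo_genome(3, 2_000_000)


@pytest.fixture(scope="session")
def plain_model():
    """Two-chromosome model without annotation (binning / placement tests)."""
    return GenomeModel(chromosomes={"chr1": 50_000_000, "chr2": 50_000_000})
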