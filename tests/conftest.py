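import numpy as np
import pytest

from megadomain.genome import GenomeLayout
from megadomain.simulate import simulate_truth


@pytest.fixture
def toy_layout() -> GenomeLayout:
    """Two small chromosomes at 250-kb bins (4 + 3 bins)."""
    return GenomeLayout(("chr1", "chr2"), (1_000_000, 750_000), 250_000)


@pytest.fixture(scope="session")
def default_truth():
    """The standard synthetic genome (labels + annotations), one per session."""
    return simulate_truth(seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
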