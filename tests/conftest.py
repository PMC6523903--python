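import numpy as np
import pytest

from methylrad.genome import generate_genome
from methylrad.synthetic import StudyDesign


@pytest.fixture(scope="session")
def small_genome():
    """300 kb single-chromosome genome shared by unit tests."""
    return generate_genome(123, 1, 300_000, 0.4)


@pytest.fixture
def design():
    return StudyDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
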