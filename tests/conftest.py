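import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from auxintor.genome import Gene, GenomeSpec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_genome() -> GenomeSpec:
    """Two chromosomes, four genes, one overlapping pair on chrII."""
    genes = [
        Gene("geneA", "chrI", 101, 200),
        Gene("geneB", "chrI", 301, 400),
        Gene("geneC", "chrII", 51, 150),
        Gene("geneD", "chrII", 120, 220),  # overlaps geneC on 120..150
    ]
    return GenomeSpec([("chrI", 500), ("chrII", 300)], genes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
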