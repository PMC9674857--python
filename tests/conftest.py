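import numpy as np
import pytest

from kinstack.genotypes import GenotypeMatrix, simulate_genotypes
from kinstack.harness import task_seed


@pytest.fixture
def tiny_panel():
    """Handcrafted 4-sample x 3-marker panel for exact-value checks."""
    calls = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [1, 2, 1],
        ]
    )
    return GenotypeMatrix(
        samples=["a", "b", "c", "d"], markers=["m1", "m2", "m3"], calls=calls
    )


@pytest.fixture(scope="session")
def small_panel():
    """Synthetic unrelated panel spanning all three MAF bands."""
    return simulate_genotypes(80, 600, (0.01, 0.5), seed=2)


@pytest.fixture(scope="session")
def family_panel():
    """Synthetic stand-in for a livestock panel: 25 families of 20, so the
    kinship matrices carry the block relatedness real breeding populations
    have."""
    return simulate_genotypes(500, 1000, (0.01, 0.5), n_families=25,
                              seed=task_seed(1, "panel"))
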