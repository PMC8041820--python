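import numpy as np
import pytest

from bemisia_delim.structure import GenotypeMatrix, PopulationMap


@pytest.fixture
def toy_matrix():
    """Six diploid individuals, four loci, one missing call."""
    dosages = np.array(
        [
            [0, 1, 2, 0],
            [0, 0, 2, 1],
            [1, 0, 2, 0],
            [2, 2, 2, 1],
            [2, 1, 2, -1],
            [1, 2, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        dosages,
        [f"ind{i}" for i in range(6)],
        [f"L{j}" for j in range(4)],
        ploidy=2,
    )


@pytest.fixture
def toy_popmap():
    return PopulationMap(
        {f"ind{i}": ("popA" if i < 3 else "popB") for i in range(6)}
    )
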