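import numpy as np
import pytest

from zonescan.scoring import ResidueAlphabet, SubstitutionMatrix, load_matrix
from zonescan.zones import SearchParams


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def identity_matrix():
    """Toy matrix: +1 on the diagonal, -1 elsewhere."""
    scores = np.full((20, 20), -1, dtype=np.int64)
    np.fill_diagonal(scores, 1)
    return SubstitutionMatrix(
        name="IDENTITY", scores=scores, alphabet=ResidueAlphabet("ARNDCQEGHILKMFPSTWYV")
    )


@pytest.fixture
def params():
    return SearchParams()
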