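import numpy as np
import pytest

from ventbeta import IncidenceMatrix


@pytest.fixture
def tiny_matrix() -> IncidenceMatrix:
    """3 sites x 4 species with a mix of shared, nested and unique species."""
    occ = np.array(
        [
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [1, 0, 0, 1],
        ],
        dtype=bool,
    )
    return IncidenceMatrix(("A", "B", "C"), ("w", "x", "y", "z"), occ)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_matrix(rng: np.random.Generator, n_sites: int = 6, n_species: int = 12,
                  p: float = 0.45) -> IncidenceMatrix:
    """A random incidence matrix guaranteed to have no empty site."""
    while True:
        occ = rng.random((n_sites, n_species)) < p
        if occ.any(axis=1).all():
            return IncidenceMatrix(
                tuple(f"s{i}" for i in range(n_sites)),
                tuple(f"sp{j}" for j in range(n_species)),
                occ,
            )
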