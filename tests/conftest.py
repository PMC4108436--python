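import numpy as np
import pytest

import bioregions as br


@pytest.fixture(scope="session")
def default_fauna():
    """One default synthetic fauna shared across tests (seed fixed)."""
    return br.generate(br.FaunaSpec(seed=11))


@pytest.fixture(scope="session")
def fitted_default(default_fauna):
    matrix, traits, sites, truth = default_fauna
    model = br.Bioregionalization(matrix, traits, sites)
    return model.fit(seed=11), truth


@pytest.fixture()
def toy_matrix():
    """3 sites x 4 species with hand-enumerable overlaps.

    A: {sp1, sp2, sp3}; B: {sp2, sp3, sp4}; C: {sp4}
    """
    inc = np.array([
        [1, 1, 1, 0],
        [0, 1, 1, 1],
        [0, 0, 0, 1],
    ], dtype=bool)
    return br.OccurrenceMatrix(["A", "B", "C"], ["sp1", "sp2", "sp3", "sp4"], inc)


@pytest.fixture()
def toy_dissimilarity():
    """3 sites with D(A,B)=0.1 and D(A,C)=D(B,C)=0.9."""
    vals = np.array([
        [0.0, 0.1, 0.9],
        [0.1, 0.0, 0.9],
        [0.9, 0.9, 0.0],
    ])
    return br.DissimilarityMatrix(["A", "B", "C"], vals)


def random_incidence(rng, n_sites, n_species, p=0.4):
    """Random occupancy matrix with no empty sites or species."""
    while True:
        inc = rng.random((n_sites, n_species)) < p
        if inc.any(axis=1).all() and inc.any(axis=0).all():
            return inc
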