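import numpy as np
import pytest

import edselect as ed


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_landscape():
    """60-site landscape with 3 latent gradients and modest noise."""
    return ed.generate_environment(
        ed.LandscapeConfig(n_sites=60, n_latent=3, noise_sd=0.3, seed=101)
    )


@pytest.fixture
def small_pa(small_landscape):
    return ed.generate_species(
        small_landscape.latent, ed.NicheConfig(n_species=25, seed=202)
    )


@pytest.fixture
def line_distances():
    """Distance matrix of four collinear sites at positions 0, 1, 2, 10."""
    pos = np.array([0.0, 1.0, 2.0, 10.0])
    return ed.DistanceMatrix(np.abs(pos[:, None] - pos[None, :]))


def random_distance_matrix(rng, n, dim=3):
    """Euclidean distances of n random points (tie-free with probability 1)."""
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(n, dim))
    return ed.DistanceMatrix(squareform(pdist(pts)))


def random_presence_absence(rng, n_sites, n_species):
    """Random binary matrix, repaired so every species occurs at least once."""
    occ = (rng.random((n_sites, n_species)) < 0.3).astype(np.int8)
    for j in np.flatnonzero(occ.sum(axis=0) == 0):
        occ[int(rng.integers(n_sites)), j] = 1
    return ed.PresenceAbsenceMatrix(
        occ=occ,
        site_ids=[f"s{i}" for i in range(n_sites)],
        species_ids=[f"sp{j}" for j in range(n_species)],
    )
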