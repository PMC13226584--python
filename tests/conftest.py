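from __future__ import annotations

import numpy as np
import pytest

from kmerbeta.synthetic_data import CommunityDesign, simulate_community


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_design():
    """Smallest community that still has environment structure."""
    return CommunityDesign(
        n_environments=2,
        samples_per_environment=2,
        pool_size=12,
        species_per_environment=4,
        shared_fraction=0.5,
        reads_per_sample=400,
        read_length=60,
        substitution_rate=0.01,
        genome_length=4_000,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_community():
    """One simulated community shared by read-only tests."""
    design = CommunityDesign(
        n_environments=2,
        samples_per_environment=3,
        pool_size=16,
        species_per_environment=5,
        shared_fraction=0.4,
        reads_per_sample=1_500,
        read_length=100,
        substitution_rate=0.01,
        genome_length=20_000,
        master_seed=42,
    )
    genomes, profiles, reads, truth = simulate_community(design)
    return design, genomes, profiles, reads, truth


def random_dissimilarity(rng: np.random.Generator, n: int, labels=None):
    """A random symmetric hollow matrix with entries in (0, 1)."""
    from kmerbeta.dissimilarity import DissimilarityMatrix

    v = rng.uniform(0.05, 0.95, size=(n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix(labels or [f"S{i}" for i in range(n)], v, "random")
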