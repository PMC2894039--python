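import numpy as np
import pytest

from consite.synthetic import (
    FixtureSpec,
    build_bead_model,
    fixture_reference_table,
    make_alignment,
    make_complex,
)


@pytest.fixture(scope="session")
def slab_spec():
    return FixtureSpec(seed=42)


@pytest.fixture(scope="session")
def slab_fixture(slab_spec):
    """Default two-slab complex with a tight planted conserved blob."""
    model, truth = make_complex(slab_spec)
    return model, truth


@pytest.fixture(scope="session")
def slab_alignment(slab_spec, slab_fixture):
    model, truth = slab_fixture
    return make_alignment(slab_spec, truth, model.subset(["A"]))


@pytest.fixture(scope="session")
def sphere_spec():
    return FixtureSpec(
        geometry="sphere-contact", n_residues_per_chain=240, interface_size=20, seed=42
    )


@pytest.fixture(scope="session")
def sphere_fixture(sphere_spec):
    model, truth = make_complex(sphere_spec)
    return model, truth


@pytest.fixture(scope="session")
def bead_reference():
    """Reference max-accessibility table for the toy two-bead residues."""
    return fixture_reference_table()


@pytest.fixture
def bead_model():
    """Factory for ad-hoc carbon-bead models."""
    return build_bead_model


def brute_force_m_s(coords):
    """Independent double-loop mean inverse pairwise distance."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1.0 / np.linalg.norm(coords[i] - coords[j])
            pairs += 1
    return total / pairs


@pytest.fixture(scope="session")
def m_s_oracle():
    return brute_force_m_s


def naive_average_linkage(coords, threshold):
    """Independent agglomerative oracle: repeatedly merge the pair of clusters
    with the smallest average inter-point distance while that distance is at
    or below the threshold."""
    coords = np.asarray(coords, dtype=float)
    clusters = [[i] for i in range(len(coords))]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    while len(clusters) > 1:
        best = None
        best_pair = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                avg = float(np.mean([d[i, j] for i in clusters[a] for j in clusters[b]]))
                if best is None or avg < best:
                    best, best_pair = avg, (a, b)
        if best is None or best > threshold:
            break
        a, b = best_pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


@pytest.fixture(scope="session")
def linkage_oracle():
    return naive_average_linkage
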