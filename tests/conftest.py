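"""Shared fixtures: synthetic structures, descriptors and a trained network.

Expensive artifacts (surface descriptors, the trained pair network) are
session-scoped so the suite computes each once.
"""

from __future__ import annotations

import numpy as np
import pytest

from zernsurf.fixtures import (
    make_blob_protein,
    make_descriptor_clusters,
    make_ideal_helix,
    make_ideal_sheet,
)
from zernsurf.similarity import NetworkConfig, train_network
from zernsurf.zernike import compute_descriptor

TEST_GRID_N = 48  # production uses 200; coarse grids keep the suite quick


@pytest.fixture(scope="session")
def helix_structure():
    return make_ideal_helix(20)


@pytest.fixture(scope="session")
def sheet_structure():
    return make_ideal_sheet(3, 8)


@pytest.fixture(scope="session")
def blob_structure():
    return make_blob_protein(30, seed=2)


@pytest.fixture(scope="session")
def fixture_structures(helix_structure, sheet_structure, blob_structure):
    return [helix_structure, sheet_structure, blob_structure]


@pytest.fixture(scope="session")
def fixture_descriptors(fixture_structures):
    return {
        s.id: compute_descriptor(s, "full_atom", order=20, N=TEST_GRID_N)
        for s in fixture_structures
    }


@pytest.fixture(scope="session")
def cluster_data():
    descs, labels = make_descriptor_clusters(
        n_folds=10, per_fold=20, separation=1.0, noise=0.15, seed=7
    )
    return descs, np.array(labels)


def sample_cluster_pairs(descs, labels, n, rng):
    """Balanced positive/negative pairs from labeled descriptors."""
    by_fold = {f: np.where(labels == f)[0] for f in set(labels)}
    folds = sorted(by_fold)
    pairs = []
    for _ in range(n // 2):
        f = folds[rng.integers(len(folds))]
        i, j = rng.choice(by_fold[f], 2, replace=False)
        pairs.append((descs[i], descs[j], 1))
    for _ in range(n // 2):
        f1, f2 = rng.choice(len(folds), 2, replace=False)
        i = rng.choice(by_fold[folds[f1]])
        j = rng.choice(by_fold[folds[f2]])
        pairs.append((descs[i], descs[j], 0))
    return pairs


@pytest.fixture(scope="session")
def cluster_pairs(cluster_data):
    descs, labels = cluster_data
    rng = np.random.default_rng(11)
    return {
        "train": sample_cluster_pairs(descs, labels, 3000, rng),
        "test": sample_cluster_pairs(descs, labels, 1000, rng),
    }


@pytest.fixture(scope="session")
def trained_network(cluster_pairs):
    params, log = train_network(cluster_pairs["train"], NetworkConfig(epochs=30, seed=3))
    return params, log
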