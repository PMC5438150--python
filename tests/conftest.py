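"""Shared fixtures and small-graph builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dlpca import CoexpressionNetwork, PathogenicAnnotation, SeedSet


def net_from_weights(W, node_ids=None, weight_cutoff=0.0, beta=1):
    W = np.asarray(W, dtype=float)
    if node_ids is None:
        node_ids = [f"g{i}" for i in range(W.shape[0])]
    return CoexpressionNetwork.from_weight_matrix(
        node_ids, W, beta=beta, weight_cutoff=weight_cutoff
    )


def random_network(rng, n, p=0.3, isolated_ok=True):
    """Random weighted undirected graph; weights uniform on (0.05, 1]."""
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < p
    w = rng.uniform(0.05, 1.0, size=iu.size)
    W[iu[present], ju[present]] = w[present]
    W += W.T
    if not isolated_ok:
        deg = (W > 0).sum(axis=1)
        for i in np.flatnonzero(deg == 0):
            j = (i + 1) % n
            W[i, j] = W[j, i] = 0.5
    return net_from_weights(W)


def manual_seed_set(seed_ids):
    return SeedSet(
        seed_ids=tuple(seed_ids), category_labels=tuple(range(len(seed_ids)))
    )


@pytest.fixture
def triangle():
    W = np.array([[0, 0.9, 0.8], [0.9, 0, 0.7], [0.8, 0.7, 0]])
    return net_from_weights(W, node_ids=["a", "b", "c"])


@pytest.fixture
def star5():
    """5-node star: hub g0 connected to g1..g4, no rim edges."""
    W = np.zeros((5, 5))
    W[0, 1:] = W[1:, 0] = 0.6
    return net_from_weights(W)


@pytest.fixture
def two_cliques():
    """Two disjoint 6-cliques over nodes a0..a5 and b0..b5."""
    W = np.zeros((12, 12))
    W[:6, :6] = 0.8
    W[6:, 6:] = 0.8
    np.fill_diagonal(W, 0.0)
    ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    return net_from_weights(W, node_ids=ids)


@pytest.fixture
def small_annotation():
    return PathogenicAnnotation(
        disease_genes=frozenset({"a0", "a1"}),
        non_disease_genes=frozenset({"b0", "b1"}),
    )
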