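"""Seed-node selection by rank product of clustering coefficient and degree.

Nodes that sit in dense neighbourhoods (high clustering coefficient) and
have many neighbours (high degree) spread labels quickly, so each of the
``m`` best-ranked nodes is given a distinct category label to nucleate a
module.  The two descending rankings are combined by their geometric mean
(the rank product), and the ``m`` smallest rank products win.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .netbuild import CoexpressionNetwork

__all__ = [
    "SeedScore",
    "SeedSet",
    "clustering_coefficient",
    "node_ranks",
    "select_seeds",
]


@dataclass(frozen=True)
class SeedScore:
    """Per-node seeding statistics: c_i, d_i, their ranks and the product."""

    node_id: str
    c: float
    d: int
    rank_c: float
    rank_d: float
    rank_product: float


@dataclass(frozen=True)
class SeedSet:
    """The ``m`` selected seeds, each carrying a distinct category label."""

    seed_ids: tuple[str, ...]
    category_labels: tuple[int, ...]
    scores: tuple[SeedScore, ...] = ()

    def __post_init__(self) -> None:
        if len(self.seed_ids) != len(self.category_labels):
            raise ValueError("one category label per seed required")
        if len(set(self.category_labels)) != len(self.category_labels):
            raise ValueError("category labels must be distinct across seeds")

    def __len__(self) -> int:
        return len(self.seed_ids)


def _clustering_coefficients(net: CoexpressionNetwork) -> np.ndarray:
    """c_i = 2 * (edges among neighbours of i) / (d_i * (d_i - 1)) for all i."""
    A = net.A.astype(float)
    d = A.sum(axis=1)
    # diagonal of A^3 counts each triangle through i twice (ordered pairs)
    closed = ((A @ A) * A).sum(axis=1)
    c = np.zeros(net.n_nodes, dtype=float)
    ok = d > 1
    c[ok] = closed[ok] / (d[ok] * (d[ok] - 1))
    return c


def clustering_coefficient(net: CoexpressionNetwork, node: str) -> float:
    """Clustering coefficient of one node.

    Defined as the fraction of neighbour pairs that are themselves
    connected; 0 for nodes of degree 0 or 1, where the ratio is
    undefined.
    """
    i = net.index(node)
    nbrs = np.flatnonzero(net.A[i])
    d = nbrs.size
    if d <= 1:
        return 0.0
    sub = net.A[np.ix_(nbrs, nbrs)]
    return float(sub.sum() / (d * (d - 1)))


def node_ranks(values) -> np.ndarray:
    """Descending fractional ranks: rank 1 is the largest value.

    Ties receive the average of the ranks they span, so the result is
    invariant under permutation of equal values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty list")
    return rankdata(-values, method="average")


def seed_scores(net: CoexpressionNetwork) -> list[SeedScore]:
    """Rank-product scores for every non-isolated node.

    Isolated nodes take no part in seeding: they can neither receive nor
    spread labels.
    """
    d = net.degrees
    keep = np.flatnonzero(d > 0)
    if keep.size == 0:
        raise ValueError("network has no non-isolated nodes")
    c = _clustering_coefficients(net)[keep]
    deg = d[keep].astype(float)
    rank_c = node_ranks(c)
    rank_d = node_ranks(deg)
    rp = np.sqrt(rank_c * rank_d)
    return [
        SeedScore(
            node_id=net.node_ids[keep[k]],
            c=float(c[k]),
            d=int(deg[k]),
            rank_c=float(rank_c[k]),
            rank_d=float(rank_d[k]),
            rank_product=float(rp[k]),
        )
        for k in range(keep.size)
    ]


def select_seeds(net: CoexpressionNetwork, m: int) -> SeedSet:
    """Select the ``m`` nodes with the smallest rank product as seeds.

    Ties at the boundary are broken lexicographically by node id so that
    selection is deterministic.  Each seed receives its own integer
    category label (0..m-1 in selection order).
    """
    if m < 1:
        raise ValueError("m must be a positive integer")
    scores = seed_scores(net)
    if m > len(scores):
        raise ValueError(
            f"m={m} exceeds the {len(scores)} non-isolated nodes available"
        )
    ordered = sorted(scores, key=lambda s: (s.rank_product, s.node_id))
    chosen = ordered[:m]
    return SeedSet(
        seed_ids=tuple(s.node_id for s in chosen),
        category_labels=tuple(range(m)),
        scores=tuple(chosen),
    )
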