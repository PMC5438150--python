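"""Weighted gene co-expression network construction.

Builds the weight matrix ``W`` (soft-thresholded absolute Pearson
correlation), the binary adjacency ``A`` and the row-stochastic transition
matrix ``P`` from a genes x samples expression table, and chooses the soft
power ``beta`` by scale-free topology fit of the resulting degree
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "ScaleFreeFit",
    "pairwise_correlation",
    "build_network",
    "scale_free_fit",
    "select_soft_threshold",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples numeric expression table.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered sample identifiers (columns).
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` with no
        missing values.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        n_genes, n_samples = len(self.gene_ids), len(self.sample_ids)
        if values.shape != (n_genes, n_samples):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{n_genes} genes x {n_samples} samples"
            )
        if n_genes < 2:
            raise ValueError("need at least 2 genes")
        if n_samples < 3:
            raise ValueError("need at least 3 samples for Pearson correlation")
        if len(set(self.gene_ids)) != n_genes:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values contain NaN or infinity")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class CoexpressionNetwork:
    """A weighted gene co-expression network over a fixed node set.

    ``W`` holds soft-thresholded edge weights in ``[0, 1]`` with zero
    diagonal, ``A`` the binary adjacency (``a_ij = 1`` iff
    ``w_ij > weight_cutoff``), and ``P`` the row-normalisation of ``W``
    (rows of isolated nodes are all zero).
    """

    node_ids: tuple[str, ...]
    W: np.ndarray
    A: np.ndarray
    P: np.ndarray
    beta: int
    weight_cutoff: float
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    @classmethod
    def from_weight_matrix(
        cls,
        node_ids,
        W: np.ndarray,
        beta: int = 1,
        weight_cutoff: float = 0.0,
    ) -> "CoexpressionNetwork":
        """Derive ``A`` and ``P`` from a symmetric weight matrix.

        Entries at or below ``weight_cutoff`` are removed before anything
        else; the diagonal is forced to zero so no node neighbours itself.
        """
        W = np.array(W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if W.min() < 0 or W.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        if not 0 <= weight_cutoff < 1:
            raise ValueError("weight_cutoff must lie in [0, 1)")
        np.fill_diagonal(W, 0.0)
        W[W <= weight_cutoff] = 0.0
        A = (W > 0).astype(np.int8)
        row_sums = W.sum(axis=1)
        P = np.zeros_like(W)
        nz = row_sums > 0
        P[nz] = W[nz] / row_sums[nz, None]
        return cls(tuple(node_ids), W, A, P, int(beta), float(weight_cutoff))

    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node: {node!r}") from None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Unweighted degree d_i of every node."""
        return self.A.sum(axis=1).astype(int)

    @property
    def weighted_connectivity(self) -> np.ndarray:
        """Weighted degree (sum of incident edge weights) of every node."""
        return self.W.sum(axis=1)

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of nodes with no neighbours."""
        return self.degrees == 0

    def neighbors(self, node: str) -> list[str]:
        i = self.index(node)
        return [self.node_ids[j] for j in np.flatnonzero(self.A[i])]


@dataclass(frozen=True)
class ScaleFreeFit:
    """R-squared and slope of the log-log degree-distribution regression."""

    beta_candidate: int
    r_squared: float
    slope: float


def pairwise_correlation(expr: ExpressionMatrix) -> np.ndarray:
    """Pearson correlation between every pair of gene expression profiles.

    Returns a symmetric matrix with unit diagonal. A gene with zero
    variance across samples makes its correlations undefined and is
    rejected by name.
    """
    variances = expr.values.var(axis=1)
    zero_var = np.flatnonzero(variances == 0)
    if zero_var.size:
        raise ValueError(
            f"gene {expr.gene_ids[zero_var[0]]!r} has zero variance across samples"
        )
    cor = np.corrcoef(expr.values)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def build_network(
    expr: ExpressionMatrix,
    beta: int,
    weight_cutoff: float = 0.1,
) -> CoexpressionNetwork:
    """Construct the co-expression network ``(W, A, P)``.

    ``w_ij = |cor(x_i, x_j)|**beta`` for ``i != j``; entries at or below
    ``weight_cutoff`` are then dropped, which defines the edge set.  With
    ``weight_cutoff = 0`` every nonzero soft-thresholded correlation is an
    edge.
    """
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    cor = pairwise_correlation(expr)
    W = np.abs(cor) ** beta
    return CoexpressionNetwork.from_weight_matrix(
        expr.gene_ids, W, beta=beta, weight_cutoff=weight_cutoff
    )


def scale_free_fit(net: CoexpressionNetwork, n_bins: int = 10) -> ScaleFreeFit:
    """Goodness of scale-free topology fit of the degree distribution.

    Degrees of non-isolated nodes are binned into ``n_bins`` equal-width
    bins on a log10 scale; empty bins are dropped and the relative
    frequency per occupied bin is regressed (log10 vs log10 of the mean
    degree in the bin).  Returns the regression R-squared and the signed
    slope; a scale-free network has R-squared near 1 and negative slope.
    """
    degrees = net.degrees
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        raise ValueError("all nodes are isolated; no degree distribution to fit")
    if np.unique(degrees).size < 2:
        raise ValueError("degenerate degree distribution: a single degree value")
    log_k = np.log10(degrees.astype(float))
    edges = np.linspace(log_k.min(), log_k.max(), n_bins + 1)
    # right-inclusive last bin so the maximum degree is counted
    which = np.clip(np.digitize(log_k, edges, right=False) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(degrees[mask].mean()))
        ys.append(np.log10(mask.sum() / degrees.size))
    if len(xs) < 2:
        raise ValueError("fewer than 2 occupied degree bins; cannot regress")
    fit = stats.linregress(xs, ys)
    return ScaleFreeFit(
        beta_candidate=net.beta,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
    )


def select_soft_threshold(
    expr: ExpressionMatrix,
    fit_target: float = 0.8,
    beta_max: int = 30,
    weight_cutoff: float = 0.1,
    n_bins: int = 10,
    direction: str = "ge",
) -> int:
    """Smallest positive integer ``beta`` whose network meets the fit target.

    ``direction='ge'`` (the WGCNA convention) accepts the first beta whose
    scale-free R-squared is at least ``fit_target``; ``direction='le'``
    accepts R-squared at most ``fit_target``.
    """
    if not 0 < fit_target <= 1:
        raise ValueError("fit_target must lie in (0, 1]")
    if beta_max < 1:
        raise ValueError("beta_max must be >= 1")
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    best: tuple[int, float] | None = None
    for beta in range(1, beta_max + 1):
        net = build_network(expr, beta=beta, weight_cutoff=weight_cutoff)
        try:
            fit = scale_free_fit(net, n_bins=n_bins)
        except ValueError:
            continue
        r2 = fit.r_squared
        ok = r2 >= fit_target if direction == "ge" else r2 <= fit_target
        if ok:
            return beta
        score = r2 if direction == "ge" else -r2
        if best is None or score > best[1]:
            best = (beta, r2)
    detail = f"best candidate beta={best[0]} with R^2={best[1]:.4f}" if best else "no usable candidate"
    raise ValueError(
        f"no beta in 1..{beta_max} reaches scale-free fit target {fit_target} "
        f"({direction}); {detail}"
    )
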