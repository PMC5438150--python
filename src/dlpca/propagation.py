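"""Double label propagation clustering (DLPCA) and the MLPA baseline.

Every node carries two labels.  The *category* label is a seed identity
propagated through the network; nodes sharing a final category label form
a module.  The *pathogenic* label is a continuous score in ``[-1, 1]``,
initialised to +1 for known disease genes, -1 for known non-disease genes
and 0 otherwise, and diffused over the transition matrix.  The two
propagations are interleaved: the pathogenic scores bias the category
vote, and the category structure splits the pathogenic diffusion into
same-module and cross-module terms.

Category update (argmax over candidate labels f_n held by >= 1 neighbour)::

    score(f_n) = lambda1 * sum_{j in N_i^{f_n}} w_ij
               + lambda2 * sum_{j in N_i^{f_n}} a_ij
               + lambda3 * sum_{j in N_i^{f_n}} l_j * l_i

Pathogenic update (beta1 + beta2 + beta3 = 1 keeps scores in [-1, 1])::

    l_i  <-  beta1 * sum_{j in N_i, same label} p_ij * l_j
           + beta2 * sum_{j in N_i, other}      p_ij * l_j
           + beta3 * l_i

Iteration stops when category labels stop changing or every node's
pathogenic change falls below a threshold (0.1 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .evaluation import ModulePartition
from .netbuild import CoexpressionNetwork
from .seeding import SeedSet, select_seeds

__all__ = [
    "UNASSIGNED",
    "PathogenicAnnotation",
    "LabelState",
    "DlpcaConfig",
    "DlpcaResult",
    "init_labels",
    "update_category_label",
    "update_pathogenic_label",
    "has_converged",
    "run_dlpca",
    "run_mlpa",
    "derive_lambda_params",
    "lambda_params_from_averages",
]

logger = logging.getLogger(__name__)

#: Sentinel category for nodes not yet captured by any seed label.
UNASSIGNED = -1


@dataclass(frozen=True)
class PathogenicAnnotation:
    """Training annotation: disjoint sets of disease and non-disease genes."""

    disease_genes: frozenset[str]
    non_disease_genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_genes", frozenset(self.disease_genes))
        object.__setattr__(self, "non_disease_genes", frozenset(self.non_disease_genes))
        overlap = self.disease_genes & self.non_disease_genes
        if overlap:
            raise ValueError(
                f"gene(s) in both disease and non-disease lists: {sorted(overlap)[:3]}"
            )

    @property
    def training_genes(self) -> frozenset[str]:
        return self.disease_genes | self.non_disease_genes


@dataclass
class LabelState:
    """Per-node category and pathogenic labels at one iteration.

    ``category`` holds the integer seed label of each node (``UNASSIGNED``
    for nodes not yet captured); ``pathogenic`` holds the continuous
    disease score in ``[-1, 1]``.  Arrays are indexed like
    ``net.node_ids``.
    """

    node_ids: tuple[str, ...]
    category: np.ndarray
    pathogenic: np.ndarray
    iteration: int = 0

    def copy(self) -> "LabelState":
        return LabelState(
            self.node_ids, self.category.copy(), self.pathogenic.copy(), self.iteration
        )

    def category_of(self, node_ids=None) -> dict[str, int]:
        return {n: int(c) for n, c in zip(self.node_ids, self.category)}

    def pathogenic_of(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.node_ids, self.pathogenic)}


@dataclass(frozen=True)
class DlpcaConfig:
    """All tunable parameters of a DLPCA/MLPA run.

    lambda1/lambda2/lambda3 weight the edge-weight, degree and pathogenic
    terms of the category vote; beta1/beta2/beta3 (summing to 1) weight
    the same-module, cross-module and inertia terms of the pathogenic
    diffusion.  ``m`` is the number of seeds.
    """

    m: int
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    beta1: float = 0.15
    beta2: float = 0.15
    beta3: float = 0.7
    pathogenic_tol: float = 0.1
    max_iter: int = 100
    schedule: str = "asynchronous"
    clamp_training_labels: bool = False
    freeze_seed_labels: bool = False
    termination: str = "or"
    tie_policy: str = "keep-current"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambda parameters must be non-negative")
        if min(self.beta1, self.beta2, self.beta3) < 0:
            raise ValueError("beta parameters must be non-negative")
        if abs(self.beta1 + self.beta2 + self.beta3 - 1.0) > 1e-9:
            raise ValueError("beta1 + beta2 + beta3 must equal 1")
        if self.pathogenic_tol <= 0:
            raise ValueError("pathogenic_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.schedule not in ("synchronous", "asynchronous"):
            raise ValueError("schedule must be 'synchronous' or 'asynchronous'")
        if self.termination not in ("or", "and"):
            raise ValueError("termination must be 'or' or 'and'")
        if self.tie_policy != "keep-current":
            raise ValueError("unknown tie policy")


@dataclass(frozen=True)
class DlpcaResult:
    """Outcome of a propagation run."""

    partition: ModulePartition
    pathogenic: dict[str, float]
    iterations: int
    converged: bool
    seeds: SeedSet
    #: per-iteration (category labels changed, max |pathogenic delta|,
    #: max |pathogenic| observed after the update)
    history: tuple[tuple[int, float, float], ...] = ()


def init_labels(
    net: CoexpressionNetwork,
    seeds: SeedSet,
    annot: PathogenicAnnotation,
) -> LabelState:
    """Initial label state: seeds own their category, training genes +-1.

    Annotation genes absent from the network are ignored with a warning;
    all remaining nodes start unassigned with pathogenic score 0.
    """
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    node_set = set(net.node_ids)
    missing = (annot.training_genes) - node_set
    if missing:
        logger.warning(
            "%d annotated gene(s) absent from the network (e.g. %s); ignored",
            len(missing),
            sorted(missing)[0],
        )
    category = np.full(net.n_nodes, UNASSIGNED, dtype=int)
    for seed, label in zip(seeds.seed_ids, seeds.category_labels):
        category[net.index(seed)] = label
    pathogenic = np.zeros(net.n_nodes, dtype=float)
    for gene in annot.disease_genes & node_set:
        pathogenic[net.index(gene)] = 1.0
    for gene in annot.non_disease_genes & node_set:
        pathogenic[net.index(gene)] = -1.0
    return LabelState(net.node_ids, category, pathogenic, iteration=0)


def _category_scores(
    net: CoexpressionNetwork,
    category: np.ndarray,
    pathogenic_prev: np.ndarray,
    cfg: DlpcaConfig,
    i: int,
    pathogenic_term: bool,
) -> dict[int, float]:
    """Eq-style vote totals per candidate label for node ``i``.

    Candidates are labels currently held by at least one neighbour;
    unassigned neighbours contribute to no candidate.
    """
    nbrs = np.flatnonzero(net.A[i])
    scores: dict[int, float] = {}
    if nbrs.size == 0:
        return scores
    labels = category[nbrs]
    labelled = labels != UNASSIGNED
    if not labelled.any():
        return scores
    nbrs = nbrs[labelled]
    labels = labels[labelled]
    w = net.W[i, nbrs]
    a = net.A[i, nbrs].astype(float)
    if pathogenic_term:
        path = pathogenic_prev[nbrs] * pathogenic_prev[i]
    else:
        path = np.zeros(nbrs.size)
    for lab in np.unique(labels):
        mask = labels == lab
        scores[int(lab)] = float(
            cfg.lambda1 * w[mask].sum()
            + cfg.lambda2 * a[mask].sum()
            + cfg.lambda3 * path[mask].sum()
        )
    return scores


def _argmax_label(scores: dict[int, float], current: int) -> int:
    """Deterministic argmax: keep the current label when it ties for the
    maximum, otherwise take the smallest seed label among the maxima."""
    if not scores:
        return UNASSIGNED
    best = max(scores.values())
    winners = [lab for lab, s in scores.items() if s >= best - 1e-12]
    if current in winners:
        return current
    return min(winners)


def update_category_label(
    net: CoexpressionNetwork,
    state: LabelState,
    cfg: DlpcaConfig,
    node: str,
) -> int:
    """New category label for one node from the three-term vote.

    Returns ``UNASSIGNED`` when the node is isolated or no neighbour
    carries a label yet (the node is retried next iteration).
    """
    i = net.index(node)
    scores = _category_scores(
        net, state.category, state.pathogenic, cfg, i, pathogenic_term=True
    )
    return _argmax_label(scores, int(state.category[i]))


def update_pathogenic_label(
    net: CoexpressionNetwork,
    state: LabelState,
    cfg: DlpcaConfig,
    node: str,
) -> float:
    """New pathogenic score for one node.

    Neighbours sharing the node's category label feed the beta1 term,
    all remaining neighbours (including unassigned ones) the beta2 term,
    and the node's own previous score the beta3 inertia term.
    """
    i = net.index(node)
    nbrs = np.flatnonzero(net.A[i])
    own = state.category[i]
    if nbrs.size == 0:
        same = np.zeros(0, dtype=bool)
    elif own == UNASSIGNED:
        same = np.zeros(nbrs.size, dtype=bool)
    else:
        same = state.category[nbrs] == own
    p = net.P[i, nbrs]
    l_prev = state.pathogenic[nbrs]
    return float(
        cfg.beta1 * (p[same] * l_prev[same]).sum()
        + cfg.beta2 * (p[~same] * l_prev[~same]).sum()
        + cfg.beta3 * state.pathogenic[i]
    )


def has_converged(prev: LabelState, cur: LabelState, cfg: DlpcaConfig) -> bool:
    """Termination test between two consecutive states.

    With ``termination='or'`` (the default) either a frozen category
    assignment or a maximal pathogenic change below ``pathogenic_tol``
    suffices; with ``'and'`` both are required.
    """
    if prev.node_ids != cur.node_ids:
        raise ValueError("states cover different node sets")
    categories_stable = bool(np.array_equal(prev.category, cur.category))
    max_delta = float(np.max(np.abs(cur.pathogenic - prev.pathogenic)))
    pathogenic_stable = max_delta < cfg.pathogenic_tol
    if cfg.termination == "or":
        return categories_stable or pathogenic_stable
    return categories_stable and pathogenic_stable


def _category_pass(
    net: CoexpressionNetwork,
    state: LabelState,
    cfg: DlpcaConfig,
    rng: np.random.Generator,
    frozen: np.ndarray,
    pathogenic_term: bool,
) -> np.ndarray:
    """One full sweep of category updates; returns the new label array."""
    order = np.flatnonzero(~net.isolated & ~frozen)
    pathogenic_prev = state.pathogenic
    if cfg.schedule == "asynchronous":
        rng.shuffle(order)
        category = state.category  # updated in place, later nodes see new labels
        for i in order:
            scores = _category_scores(
                net, category, pathogenic_prev, cfg, i, pathogenic_term
            )
            category[i] = _argmax_label(scores, int(category[i]))
        return category
    old = state.category.copy()
    new = state.category
    for i in order:
        scores = _category_scores(net, old, pathogenic_prev, cfg, i, pathogenic_term)
        new[i] = _argmax_label(scores, int(old[i]))
    return new


def _pathogenic_pass(
    net: CoexpressionNetwork,
    state: LabelState,
    cfg: DlpcaConfig,
    clamp_values: np.ndarray | None,
) -> np.ndarray:
    """One synchronous sweep of pathogenic updates (all from l^{t-1})."""
    l_prev = state.pathogenic
    category = state.category
    same = (category[:, None] == category[None, :]) & (category[:, None] != UNASSIGNED)
    contrib = net.P * l_prev[None, :]
    same_sum = (contrib * same).sum(axis=1)
    diff_sum = (contrib * ~same).sum(axis=1)
    new = cfg.beta1 * same_sum + cfg.beta2 * diff_sum + cfg.beta3 * l_prev
    if clamp_values is not None:
        mask = ~np.isnan(clamp_values)
        new[mask] = clamp_values[mask]
    return new


def _partition_from_state(
    net: CoexpressionNetwork, state: LabelState
) -> ModulePartition:
    """Nodes sharing a final category label form a module; the rest scatter."""
    assignment: dict[str, int] = {}
    scatters: set[str] = set()
    for idx, node in enumerate(net.node_ids):
        lab = int(state.category[idx])
        if lab == UNASSIGNED:
            scatters.add(node)
        else:
            assignment[node] = lab
    return ModulePartition(assignment=assignment, scatters=frozenset(scatters))


def _run(
    net: CoexpressionNetwork,
    annot: PathogenicAnnotation | None,
    cfg: DlpcaConfig,
    seeds: SeedSet | None,
    pathogenic_term: bool,
    update_pathogenic: bool,
) -> DlpcaResult:
    if seeds is None:
        seeds = select_seeds(net, cfg.m)
    if annot is None:
        annot = PathogenicAnnotation(frozenset(), frozenset())
    state = init_labels(net, seeds, annot)
    rng = np.random.default_rng(cfg.rng_seed)

    frozen = np.zeros(net.n_nodes, dtype=bool)
    if cfg.freeze_seed_labels:
        for seed in seeds.seed_ids:
            frozen[net.index(seed)] = True

    clamp_values = None
    if cfg.clamp_training_labels:
        clamp_values = np.full(net.n_nodes, np.nan)
        node_set = set(net.node_ids)
        for gene in annot.disease_genes & node_set:
            clamp_values[net.index(gene)] = 1.0
        for gene in annot.non_disease_genes & node_set:
            clamp_values[net.index(gene)] = -1.0

    history: list[tuple[int, float, float]] = []
    converged = False
    iteration = 0
    for iteration in range(1, cfg.max_iter + 1):
        prev = state.copy()
        state.category = _category_pass(
            net, state, cfg, rng, frozen, pathogenic_term
        )
        if update_pathogenic:
            state.pathogenic = _pathogenic_pass(net, state, cfg, clamp_values)
        state.iteration = iteration
        n_changed = int(np.sum(state.category != prev.category))
        max_delta = float(np.max(np.abs(state.pathogenic - prev.pathogenic)))
        history.append((n_changed, max_delta, float(np.max(np.abs(state.pathogenic)))))
        logger.info(
            "iteration %d: %d category changes, max pathogenic delta %.4g",
            iteration,
            n_changed,
            max_delta,
        )
        if update_pathogenic:
            done = has_converged(prev, state, cfg)
        else:
            done = n_changed == 0
        if done:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"propagation did not converge within max_iter={cfg.max_iter}",
            RuntimeWarning,
            stacklevel=2,
        )
    return DlpcaResult(
        partition=_partition_from_state(net, state),
        pathogenic=state.pathogenic_of(),
        iterations=iteration,
        converged=converged,
        seeds=seeds,
        history=tuple(history),
    )


def run_dlpca(
    net: CoexpressionNetwork,
    annot: PathogenicAnnotation,
    cfg: DlpcaConfig,
    seeds: SeedSet | None = None,
) -> DlpcaResult:
    """Full double label propagation run.

    Selects seeds (unless given), initialises both label families, then
    alternates one category sweep and one pathogenic sweep per iteration
    until the termination condition or ``max_iter``.  Non-convergence is
    a warning, not an error.
    """
    return _run(
        net, annot, cfg, seeds, pathogenic_term=True, update_pathogenic=True
    )


def run_mlpa(
    net: CoexpressionNetwork,
    cfg: DlpcaConfig,
    seeds: SeedSet | None = None,
) -> DlpcaResult:
    """Plain multi-label propagation baseline.

    The category vote keeps only the edge-weight (lambda1) term and there
    is no pathogenic diffusion; iteration stops when category labels stop
    changing.  Equivalent to ``run_dlpca`` with ``lambda2 = lambda3 = 0``
    under the same seeds, schedule and tie policy.
    """
    cfg = replace(cfg, lambda2=0.0, lambda3=0.0)
    return _run(
        net, None, cfg, seeds, pathogenic_term=False, update_pathogenic=False
    )


def lambda_params_from_averages(
    mean_degree: float,
    mean_weighted_connectivity: float,
    mean_abs_pathogenic: float | None = None,
) -> tuple[float, float, float]:
    """Category-vote weights from network-level averages.

    With the three vote terms meant to pull equally, lambda2 is fixed at 1,
    lambda1 is the ratio of average degree to average weighted connectivity
    (rounded to 2 decimals) so the weight term matches the degree term in
    magnitude, and lambda3 is 1 over the squared mean absolute pathogenic
    score, scaling the product ``l_j * l_i`` up to unit order.
    """
    if mean_weighted_connectivity <= 0:
        raise ValueError("mean weighted connectivity must be positive")
    lambda1 = round(mean_degree / mean_weighted_connectivity, 2)
    if mean_abs_pathogenic is None:
        return lambda1, 1.0, 1.0
    if mean_abs_pathogenic <= 0:
        raise ValueError("mean absolute pathogenic score must be positive")
    lambda3 = round(1.0 / mean_abs_pathogenic**2, 2)
    return lambda1, 1.0, lambda3


def derive_lambda_params(
    net: CoexpressionNetwork,
    pathogenic: dict[str, float],
) -> tuple[float, float, float]:
    """Derive (lambda1, lambda2, lambda3) from a network and its scores.

    Averages run over all nodes.  ``pathogenic`` is typically the score
    map after a propagation pass (or the initial +-1/0 labels).
    """
    if net.n_nodes == 0 or not (~net.isolated).any():
        raise ValueError("network has no non-isolated node")
    mean_degree = float(net.degrees.mean())
    mean_wc = float(net.weighted_connectivity.mean())
    values = np.array([abs(pathogenic.get(n, 0.0)) for n in net.node_ids])
    return lambda_params_from_averages(mean_degree, mean_wc, float(values.mean()))
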