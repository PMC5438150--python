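"""Synthetic expression matrices and planted-partition networks.

Two generators feed the test and validation pipeline:

* ``generate_expression`` draws a latent sample-profile per module and
  builds member genes as loading * latent + Gaussian noise, with the
  loading chosen so the expected within-module Pearson correlation hits a
  target.  Background genes are pure noise.
* ``generate_planted_network`` skips correlation estimation entirely and
  plants the block structure directly in a weighted random graph
  (within-module edges dense and heavy, between-module sparse and light).

Both attach a ground-truth module map and a disease/non-disease training
annotation with configurable per-module disease enrichment, and both are
fully deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netbuild import CoexpressionNetwork, ExpressionMatrix
from .propagation import PathogenicAnnotation

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_expression",
    "generate_planted_network",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generators.

    Defaults emulate a small disease-gene module study: four modules of 50
    genes over 32 samples (four genotypes x eight replicates worth of
    arrays), strong within-module co-expression, partial training
    annotation concentrated in module genes, and one disease-enriched
    module (80% of its training genes diseased vs 10% elsewhere).
    """

    n_modules: int = 4
    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    n_samples: int = 32
    within_cor: float = 0.8
    noise_sd: float = 0.3
    n_background: int = 40
    disease_fraction_per_module: tuple[float, ...] = (0.8, 0.1, 0.1, 0.1)
    training_fraction: float = 0.25
    background_training_fraction: float = 0.0
    background_disease_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        object.__setattr__(
            self,
            "disease_fraction_per_module",
            tuple(self.disease_fraction_per_module),
        )
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if len(self.disease_fraction_per_module) != self.n_modules:
            raise ValueError("disease_fraction_per_module length must equal n_modules")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module_sizes entries must be positive")
        if not 0 < self.within_cor < 1:
            raise ValueError("within_cor must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if any(not 0 <= f <= 1 for f in self.disease_fraction_per_module):
            raise ValueError("disease fractions must lie in [0, 1]")
        if not 0 < self.training_fraction <= 1:
            raise ValueError("training_fraction must lie in (0, 1]")
        if not 0 <= self.background_training_fraction <= 1:
            raise ValueError("background_training_fraction must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth attached to a generated dataset."""

    module_of: dict[str, str]
    disease_genes: frozenset[str]
    non_disease_genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease_genes", frozenset(self.disease_genes))
        object.__setattr__(self, "non_disease_genes", frozenset(self.non_disease_genes))
        if self.disease_genes & self.non_disease_genes:
            raise ValueError("disease and non-disease training sets overlap")

    @property
    def annotation(self) -> PathogenicAnnotation:
        return PathogenicAnnotation(self.disease_genes, self.non_disease_genes)

    def module_labels(self, node_ids) -> list[str]:
        """Planted module id per node, in the given order."""
        return [self.module_of[n] for n in node_ids]


def _gene_ids(spec: SyntheticSpec) -> tuple[list[str], dict[str, str]]:
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    for m, size in enumerate(spec.module_sizes):
        for g in range(size):
            gid = f"M{m + 1}G{g + 1:03d}"
            gene_ids.append(gid)
            module_of[gid] = f"module{m + 1}"
    for g in range(spec.n_background):
        gid = f"BG{g + 1:03d}"
        gene_ids.append(gid)
        module_of[gid] = BACKGROUND
    return gene_ids, module_of


def _draw_training(
    spec: SyntheticSpec,
    module_of: dict[str, str],
    rng: np.random.Generator,
) -> tuple[set[str], set[str]]:
    """Sample training genes per module and split them disease/non-disease."""
    disease: set[str] = set()
    non_disease: set[str] = set()
    for m in range(spec.n_modules):
        members = sorted(g for g, mod in module_of.items() if mod == f"module{m + 1}")
        n_train = int(round(spec.training_fraction * len(members)))
        train = rng.choice(members, size=n_train, replace=False)
        n_dis = int(round(spec.disease_fraction_per_module[m] * n_train))
        disease.update(train[:n_dis])
        non_disease.update(train[n_dis:])
    bg = sorted(g for g, mod in module_of.items() if mod == BACKGROUND)
    n_train = int(round(spec.background_training_fraction * len(bg)))
    if n_train:
        train = rng.choice(bg, size=n_train, replace=False)
        n_dis = int(round(spec.background_disease_fraction * n_train))
        disease.update(train[:n_dis])
        non_disease.update(train[n_dis:])
    return disease, non_disease


def generate_expression(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Factor-model expression matrix with planted co-expression modules.

    Each module has one latent standard-normal sample profile z_m; member
    genes are a * z_m + eps with eps ~ N(0, noise_sd^2) and the loading
    ``a`` solved from a^2 / (a^2 + noise_sd^2) = within_cor, so the
    expected correlation of two module mates equals ``within_cor``.
    """
    if spec.n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = np.random.default_rng(spec.rng_seed)
    gene_ids, module_of = _gene_ids(spec)
    loading = spec.noise_sd * np.sqrt(spec.within_cor / (1.0 - spec.within_cor))
    values = np.empty((len(gene_ids), spec.n_samples))
    row = 0
    for m, size in enumerate(spec.module_sizes):
        latent = rng.standard_normal(spec.n_samples)
        noise = rng.normal(scale=spec.noise_sd, size=(size, spec.n_samples))
        values[row : row + size] = loading * latent + noise
        row += size
    if spec.n_background:
        values[row:] = rng.normal(
            scale=spec.noise_sd, size=(spec.n_background, spec.n_samples)
        )
    expr = ExpressionMatrix(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(f"S{s + 1:02d}" for s in range(spec.n_samples)),
        values=values,
    )
    disease, non_disease = _draw_training(spec, module_of, rng)
    return expr, SyntheticTruth(module_of, frozenset(disease), frozenset(non_disease))


def generate_planted_network(
    spec: SyntheticSpec,
    p_in: float = 0.3,
    p_out: float = 0.01,
    w_in: tuple[float, float] = (0.5, 1.0),
    w_out: tuple[float, float] = (0.05, 0.2),
) -> tuple[CoexpressionNetwork, SyntheticTruth]:
    """Weighted planted-partition network with known block structure.

    Each within-module pair is connected with probability ``p_in`` and a
    weight uniform on ``w_in``; each between-module (or background) pair
    with probability ``p_out`` and weight uniform on ``w_out``.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    for lo, hi in (w_in, w_out):
        if not 0 < lo <= hi <= 1:
            raise ValueError("weight ranges must lie within (0, 1]")
    rng = np.random.default_rng(spec.rng_seed)
    gene_ids, module_of = _gene_ids(spec)
    n = len(gene_ids)
    blocks = np.array([module_of[g] for g in gene_ids])
    iu, ju = np.triu_indices(n, k=1)
    within = (blocks[iu] == blocks[ju]) & (blocks[iu] != BACKGROUND)
    prob = np.where(within, p_in, p_out)
    present = rng.random(iu.size) < prob
    weight = np.where(
        within,
        rng.uniform(w_in[0], w_in[1], size=iu.size),
        rng.uniform(w_out[0], w_out[1], size=iu.size),
    )
    W = np.zeros((n, n))
    W[iu[present], ju[present]] = weight[present]
    W += W.T
    net = CoexpressionNetwork.from_weight_matrix(
        gene_ids, W, beta=1, weight_cutoff=0.0
    )
    disease, non_disease = _draw_training(spec, module_of, rng)
    return net, SyntheticTruth(module_of, frozenset(disease), frozenset(non_disease))
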