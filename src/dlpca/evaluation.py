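"""Clustering quality metrics for module partitions.

Coverage measures how much of the network ends up in modules; module
significance measures how strongly a module concentrates known disease
genes among its training-set members.  A module with no training genes has
undefined significance (reported as ``None``), so averages run over defined
values only.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ModulePartition",
    "EvaluationReport",
    "coverage",
    "module_significance",
    "scatter_significance",
    "summarize",
]


@dataclass(frozen=True)
class ModulePartition:
    """Final node -> module assignment plus the unassigned scatters."""

    assignment: dict[str, int]
    scatters: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "scatters", frozenset(self.scatters))
        overlap = set(self.assignment) & self.scatters
        if overlap:
            raise ValueError(f"nodes both assigned and scattered: {sorted(overlap)[:3]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.assignment) | set(self.scatters)

    @property
    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


@dataclass(frozen=True)
class EvaluationReport:
    """Coverage/significance summary of one partition.

    ``module_rows`` holds one tuple per module:
    ``(module_id, size, training_genes, disease_genes, significance)``
    with ``significance`` ``None`` when the module has no training genes.
    """

    coverage: float
    module_rows: tuple[tuple[int, int, int, int, float | None], ...]
    scatter_significance: float | None
    disease_module_count: int
    avg_disease_module_size: float | None
    avg_disease_module_significance: float | None
    disease_threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "modules": [
                {
                    "module_id": mid,
                    "size": size,
                    "training_genes": n_train,
                    "disease_genes": n_dis,
                    "significance": sig,
                }
                for mid, size, n_train, n_dis, sig in self.module_rows
            ],
            "scatter_significance": self.scatter_significance,
            "disease_module_count": self.disease_module_count,
            "avg_disease_module_size": self.avg_disease_module_size,
            "avg_disease_module_significance": self.avg_disease_module_significance,
            "disease_threshold": self.disease_threshold,
        }


def coverage(partition: ModulePartition) -> float:
    """Fraction of all network nodes assigned to some module."""
    total = len(partition.nodes)
    if total == 0:
        raise ValueError("empty partition: no nodes")
    return len(partition.assignment) / total


def module_significance(module_nodes, annot) -> float | None:
    """Disease genes over training genes inside the module.

    ``None`` when the module contains no training gene (ratio undefined).
    """
    nodes = set(module_nodes)
    disease = len(nodes & annot.disease_genes)
    training = disease + len(nodes & annot.non_disease_genes)
    if training == 0:
        return None
    return disease / training


def scatter_significance(scatters, annot) -> float | None:
    """Same disease-over-training ratio, computed over the scatter set."""
    return module_significance(scatters, annot)


def summarize(
    partition: ModulePartition,
    annot,
    disease_threshold: float = 0.5,
) -> EvaluationReport:
    """Full evaluation report over a partition.

    A module counts as disease-related when its significance is defined
    and at least ``disease_threshold``; the disease-module aggregates
    (count, mean size, mean significance) run over those modules.
    """
    if not 0 <= disease_threshold <= 1:
        raise ValueError("disease_threshold must lie in [0, 1]")
    rows = []
    disease_sizes: list[int] = []
    disease_sigs: list[float] = []
    for mid in sorted(partition.modules):
        nodes = partition.modules[mid]
        disease = len(nodes & annot.disease_genes)
        training = disease + len(nodes & annot.non_disease_genes)
        sig = module_significance(nodes, annot)
        rows.append((mid, len(nodes), training, disease, sig))
        if sig is not None and sig >= disease_threshold:
            disease_sizes.append(len(nodes))
            disease_sigs.append(sig)
    return EvaluationReport(
        coverage=coverage(partition),
        module_rows=tuple(rows),
        scatter_significance=scatter_significance(partition.scatters, annot),
        disease_module_count=len(disease_sigs),
        avg_disease_module_size=(
            sum(disease_sizes) / len(disease_sizes) if disease_sizes else None
        ),
        avg_disease_module_significance=(
            sum(disease_sigs) / len(disease_sigs) if disease_sigs else None
        ),
        disease_threshold=disease_threshold,
    )
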