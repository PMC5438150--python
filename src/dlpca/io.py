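"""Readers and writers for the plain-text formats the pipeline uses.

Expression matrices are tab-separated with a header row of sample ids and
gene ids in the first column.  Networks travel as undirected weighted edge
lists (gene_a, gene_b, weight; each pair once, lexicographic).  Gene lists
are one identifier per line with ``#`` comments.  Run outputs are a module
table (TSV), an evaluation report (JSON) and a reproducibility manifest
(JSON).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, ModulePartition
from .netbuild import CoexpressionNetwork, ExpressionMatrix
from .propagation import PathogenicAnnotation

__all__ = [
    "RunManifest",
    "read_expression",
    "write_expression",
    "read_gene_lists",
    "write_gene_list",
    "read_edge_list",
    "write_edge_list",
    "read_module_table",
    "write_outputs",
]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run exactly."""

    inputs: dict[str, str]
    config: dict
    version: str
    rng_seed: int
    started: str
    finished: str
    converged: bool
    iterations: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def read_expression(path) -> ExpressionMatrix:
    """Parse a tab-separated expression table (genes x samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    genes = [str(g) for g in df.index]
    dup_mask = df.index.duplicated()
    if dup_mask.any():
        pos = int(np.flatnonzero(dup_mask)[0])
        line = pos + 2  # +1 header, +1 one-based
        raise ValueError(
            f"duplicate gene id {genes[pos]!r} at line {line} of {path}"
        )
    values = df.to_numpy()
    bad = np.argwhere(~np.isfinite(pd.to_numeric(values.ravel(), errors="coerce")
                                   .reshape(values.shape)
                                   if values.dtype == object else values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric or missing value for gene {genes[r]!r}, "
            f"sample {df.columns[c]!r} (line {r + 2}) in {path}"
        )
    return ExpressionMatrix(
        gene_ids=tuple(genes),
        sample_ids=tuple(str(s) for s in df.columns),
        values=values.astype(float),
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=list(expr.gene_ids), columns=list(expr.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def _read_id_list(path) -> list[str]:
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def read_gene_lists(disease_path, non_disease_path) -> PathogenicAnnotation:
    """Load the disease / non-disease training gene lists.

    A gene appearing in both lists is a contradiction and is rejected by
    name (via the annotation's disjointness invariant).
    """
    return PathogenicAnnotation(
        disease_genes=frozenset(_read_id_list(disease_path)),
        non_disease_genes=frozenset(_read_id_list(non_disease_path)),
    )


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_edge_list(net: CoexpressionNetwork, path) -> None:
    """Write the network as an undirected weighted edge list.

    Each edge appears once with endpoints in lexicographic order; rows are
    sorted.  Isolated nodes do not appear (the format carries edges only).
    """
    rows = []
    for i, j in zip(*np.nonzero(np.triu(net.W, k=1))):
        a, b = sorted((net.node_ids[i], net.node_ids[j]))
        rows.append((a, b, net.W[i, j]))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edge_list(path, beta: int = 1, weight_cutoff: float = 0.0) -> CoexpressionNetwork:
    """Load a weighted edge list into a network.

    The node set is the union of endpoint ids (sorted); ``A`` and ``P``
    are re-derived from the weights.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_a, gene_b, weight")
    nodes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    index = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for a, b, w in df.itertuples(index=False):
        W[index[a], index[b]] = w
        W[index[b], index[a]] = w
    return CoexpressionNetwork.from_weight_matrix(
        nodes, W, beta=beta, weight_cutoff=weight_cutoff
    )


def read_module_table(path) -> tuple[ModulePartition, dict[str, float]]:
    """Load a module table back into a partition and pathogenic map."""
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str})
    assignment: dict[str, int] = {}
    scatters: set[str] = set()
    pathogenic: dict[str, float] = {}
    for node, module, score in df.itertuples(index=False):
        pathogenic[node] = float(score)
        if module == "scatter":
            scatters.add(node)
        else:
            assignment[node] = int(module)
    return ModulePartition(assignment, frozenset(scatters)), pathogenic


def write_outputs(
    partition: ModulePartition,
    pathogenic: dict[str, float],
    report: EvaluationReport | None,
    manifest: RunManifest,
    out_dir,
) -> dict[str, Path]:
    """Write module table, evaluation report and manifest into ``out_dir``.

    Row order is node id, so two runs with identical inputs produce
    byte-identical tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"modules": out_dir / "modules.tsv", "manifest": out_dir / "manifest.json"}

    with open(paths["modules"], "w") as fh:
        fh.write("node_id\tmodule_id\tpathogenic_score\n")
        for node in sorted(partition.nodes):
            module = partition.assignment.get(node, "scatter")
            fh.write(f"{node}\t{module}\t{pathogenic.get(node, 0.0):.10g}\n")

    if report is not None:
        paths["report"] = out_dir / "report.json"
        paths["report"].write_text(json.dumps(report.to_dict(), indent=2) + "\n")

    tmp = paths["manifest"].with_suffix(".json.tmp")
    tmp.write_text(manifest.to_json() + "\n")
    tmp.replace(paths["manifest"])
    return paths


def utc_now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
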