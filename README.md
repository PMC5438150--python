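# dlpca

Detection of disease-related gene modules in weighted gene co-expression
networks by **double label propagation clustering** (DLPCA), with the plain
multi-label propagation (MLPA) baseline, rank-product seed selection,
evaluation metrics and a synthetic planted-module generator.

## The problem

Genes that share expression patterns tend to be co-regulated, so a gene
co-expression network — nodes are genes, edge weights are expression
similarity — organises into modules that often correspond to biological
mechanisms. When a small training set of known disease and non-disease
genes is available (for example modifier screens in a neurodegeneration
model), one wants modules that *concentrate* the disease genes, because
those modules nominate the pathways driving the phenotype. Plain label
propagation clusters the network fast, but ignores the annotation and
tends to produce many small modules that mix disease and non-disease
genes.

## The method

From a genes × samples expression matrix the package builds

- weights `w_ij = |cor(x_i, x_j)|^β` (Pearson; the soft power β is the
  smallest integer whose network reaches a scale-free topology fit R² ≥
  0.8), with a configurable weight cutoff defining the edge set,
- the binary adjacency `A` and the row-stochastic transition matrix
  `P = W / rowsum(W)`.

Seeds are the `m` nodes with the smallest rank product
`R_i = sqrt(R_c(i) · R_d(i))` of their descending ranks by clustering
coefficient `c_i` and degree `d_i`; each seed starts a distinct category
label. Every node also carries a continuous *pathogenic* score
`l_i ∈ [−1, 1]`, initialised to +1 (disease gene), −1 (non-disease gene)
or 0.

Each iteration then alternates:

1. **Category vote.** Node `i` adopts the label maximising
   `λ₁ Σ w_ij + λ₂ Σ a_ij + λ₃ Σ l_j·l_i` over its neighbours carrying
   each candidate label — edge weight, neighbour count and pathogenic
   agreement pulling together.
2. **Pathogenic diffusion.**
   `l_i ← β₁ Σ_same p_ij l_j + β₂ Σ_other p_ij l_j + β₃ l_i`, with the
   same-module / cross-module split taken from the current category
   labels and `β₁+β₂+β₃ = 1` keeping scores bounded.

Iteration stops when category labels freeze or every pathogenic change
drops below a threshold (0.1 by default). Nodes sharing a final category
label form a module; unlabeled and isolated nodes are *scatters*.
Modules are scored by **significance** — the fraction of their
training-set genes that are disease genes — plus network **coverage** and
scatter significance.

## Worked example

Simulate a dataset with four planted co-expression modules (30 genes
each, 20 background genes, 32 samples), one module disease-enriched, then
run the full pipeline:

```bash
dlpca simulate --n-modules 4 --module-size 30 --disease-fractions 0.8,0.1,0.1,0.1 \
    --n-background 20 --n-samples 32 --rng-seed 11 --out-dir data
dlpca build-net --expr data/expression.tsv --beta 2 --weight-cutoff 0.1 --out net.tsv
dlpca run --net net.tsv --disease data/disease_genes.txt \
    --non-disease data/non_disease_genes.txt -m 30 --lambda1 1.5 --lambda3 18 \
    --pathogenic-tol 0.001 --rng-seed 11 --out-dir run
dlpca evaluate --modules run/modules.tsv --disease data/disease_genes.txt \
    --non-disease data/non_disease_genes.txt
```

The run summary reports convergence in 5 iterations with full coverage,
and the evaluation report reads (abridged):

```json
{
  "coverage": 1.0,
  "modules": [
    {"module_id": 10, "size": 35, "training_genes": 8,  "disease_genes": 1, "significance": 0.125},
    {"module_id": 18, "size": 70, "training_genes": 16, "disease_genes": 2, "significance": 0.125},
    {"module_id": 23, "size": 35, "training_genes": 8,  "disease_genes": 6, "significance": 0.75}
  ],
  "disease_module_count": 1,
  "avg_disease_module_significance": 0.75
}
```

Module 23 recovers the planted disease-enriched block: 6 of its 8
training genes are disease genes (significance 0.75), while the other
modules sit at 0.125 — the pathogenic labels have steered the clustering
toward a partition that isolates the disease signal. The same analysis is
available as library calls (`build_network`, `select_seeds`, `run_dlpca`,
`summarize`); see the module docstrings.

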