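# ctinet — cell-type-specific interactome networks

Tissues are mixtures of cell types that deploy the same genome through
different interaction wiring. `ctinet` is an analysis toolkit for
carving **cell-type-specific interactome networks** out of a global
reference interactome using labeled single-cell expression, and for
asking the questions those networks enable: which genes are influential
in a cell type's wiring beyond being highly expressed, how similar two
cell types' networks are, which cell type a gene signature acts in, and
which genes a propagation process prioritizes from a seed list. It is
aimed at computational biologists working with scRNA-seq and
protein/gene interaction resources (STRING-like edge lists).

## Method in brief

Given a reference interactome G = (V, E) and a cells × genes UMI matrix
with cell-type labels:

1. **Transcriptional specificity.** On log1p(CP10K) values, each gene ×
   cell type gets a Welch contrast
   `tranS(i) = (x_ct − x_else) / sqrt(s²_ct/n_ct + s²_else/n_else)`,
   mapped to normal scores z_i by a rank-inverse-normal transform.
2. **Reconstruction.** Each reference edge gets
   `z_ij = (z_i + z_j)/√2`; upper-tail normal p-values are BH-corrected
   per cell type and edges with q ≤ 0.05, z_ij > 0 are kept with weight
   w_ij = z_ij (cell types need ≥ 100 cells).
3. **Topological specificity.** `topS(i) = (w(i) − μ_R(i)) / σ_R(i)`
   against a null that reshuffles edge weights over the fixed topology
   (Monte-Carlo or exact finite-population moments), with
   `topS_transf = 1/(1+e^(−topS))`.
4. **Similarity.** Spearman correlations of shared-edge weights and of
   topS_transf over shared nodes.
5. **Gene sets.** Within-group connectivity
   `C(S) = Σ_{(i,j)⊆S} w_ij / |S ∩ V|` with a uniform-subsampling
   permutation p-value; hypergeometric enrichment with BH; hub and
   neighbor rankings by weighted degree.
6. **Prioritization and benchmarking.** Random walk with restart,
   `p^{t+1} = (1−γ)Wp^t + γp⁰` (γ = 0.5, L1 tolerance 1e-10), and
   gene-set recovery AUPRC scored against degree-matched rewired nulls:
   performance = robust z of the true AUPRC, gain = relative excess
   over the null median.

A synthetic-data module generates reference networks, NB-distributed
UMI counts with planted connected cell-type modules, and matched gene
sets, so every stage has a parameter-recovery test with known ground
truth. See `docs/methods.md` for assumptions, defaults, and
limitations.

## Worked example

```python
import ctinet as ct

ref = ct.generate_reference_network(10_000, mean_degree=6, seed=1)
expr, truth = ct.generate_expression(
    ref, [("A", 500), ("B", 500), ("C", 500)],
    module_size=20, module_log2fc=2.0, seed=2,
)
networks, profile = ct.reconstruct_all(ref, expr)
netA = networks["A"]
internal = truth.module_subgraph_edges["A"]
print(netA.n_nodes, netA.n_edges, len(internal & netA.edges) / len(internal))
```

prints

```
33 36 1.0
```

the cell-type-A network keeps 36 edges over 33 genes at q ≤ 0.05, and
recalls all of the planted module's 23 reference edges. Continuing with
the dense (unthresholded positive-specificity) network:

```python
dense = ct.reconstruct_cell_type_network(ref, profile, "A",
                                         ct.RunConfig(alpha_edge_q=1.0))
res = ct.connectivity_permutation_test(dense, ct.GeneSet("mod", "", truth.planted_modules["A"]),
                                       n_permutations=1000, seed=5)
print(round(res.empirical_p, 4), round(res.z, 1))
```

```
0.001 301.3
```

the planted module is far more internally connected in its own
cell-type network than 1000 size-matched random gene sets (empirical
p = 1/1001, z ≈ 301).

## Analysis pipeline

The numbered drivers under `analysis/` run the full study on synthetic
data and write small tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate.py` | generate reference, counts, gene sets; write exchange formats |
| `02_reconstruct.py` | per-cell-type networks; planted-edge recall |
| `03_topology.py` | topS per network; topS vs tranS rank comparison |
| `04_compare.py` | pairwise similarity, replicate panel, intersection |
| `05_geneset.py` | connectivity deconvolution, enrichment, hub rankings |
| `06_prioritize.py` | RWR recovery and performance vs degree-matched nulls |

Each takes `--seed` (default 7) and `--quiet`. On the default seed the
pipeline recalls 100% of planted module edges in all three cell types,
planted markers score mean topS ≈ 9.6–10.3 in their own network versus
≈ 0 elsewhere, held-out module genes rank in the top 0.35% of RWR
candidates, and every cell-type network beats its 20 rewired nulls
(gain ≥ 49.9, performance ≥ 150.7).

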