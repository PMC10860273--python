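# Methods

`ctinet` reconstructs cell-type-specific interactome networks from
labeled single-cell expression against a reference interactome, then
quantifies gene influence, network similarity, gene-set cohesion, and
propagation-based gene priority on those networks. This note records
the model, the defaults and why they are set where they are, what the
synthetic data does and does not emulate, and the numerical choices.

## Model and procedure

**Reference interactome.** An undirected graph over gene symbols,
optionally carrying a non-negative confidence weight per edge. Gene
identifiers are opaque case-sensitive strings; symbol aliasing is a
curation concern outside the method. Confidence weights are read and
written but do not enter reconstruction: the reconstruction statistic
is expression-driven, and mixing database confidence into it would
conflate two unrelated notions of evidence.

**Transcriptional specificity (tranS).** Counts are normalized to
10,000 per cell and log1p-transformed (CP10K), pinning one standard
single-cell convention. For gene *i* and cell type *ct*,

    tranS(i) = (x_ct(i) − x_else(i)) / sqrt(s²_ct(i)/n_ct + s²_else(i)/n_else)

a Welch-style contrast of the gene's mean expression in the cell type
against all other cells. Group means, variances and sizes are retained
on the profile object so any score can be audited.

**Reconstruction.** tranS scores are mapped to normal scores within
each cell type by a rank-inverse-normal transform, z_i =
Φ⁻¹((r_i − 0.5)/G) with average ranks for ties (an all-equal input maps
exactly to zero). Each reference edge (i, j) with both endpoints
measured receives the Stouffer statistic z_ij = (z_i + z_j)/√2 and an
upper-tail normal p-value; Benjamini–Hochberg runs per cell type across
the tested edges, and edges with q ≤ `alpha_edge_q` and z_ij > 0 are
retained with weight w_ij = z_ij. The combiner is deliberately a
closed-form statistic rather than a subsampling ensemble — it is
deterministic, cheap, and testable against hand computation — and it is
exposed as a pluggable function for anyone who wants a different edge
model. Only cell types with at least `min_cells` (default 100) cells
are eligible.

Two operating points of the same procedure are used downstream:

* the **significant network** (q ≤ 0.05) — the deliverable per cell
  type, and the object scored for planted-edge recall;
* the **dense network** (`alpha_edge_q = 1.0`, i.e. every
  positive-specificity edge) — the substrate for topology scores,
  similarity, connectivity and propagation. These statistics carry
  their own nulls (weight reshuffling, set permutation, degree-matched
  rewiring), so pre-filtering edges by significance would only shrink
  their support; on clean synthetic nulls the q ≤ 0.05 network
  collapses to little more than the planted module itself, which is a
  feature of the simulation's sharp null, not of real tissues.

**Topological specificity (topS).** For node *i*, w(i) is the summed
weight of incident edges. The null keeps the topology fixed and
uniformly reshuffles the multiset of edge weights; topS(i) =
(w(i) − μ_R(i))/σ_R(i). The null moments come either from Monte-Carlo
permutations or in closed form from sampling-without-replacement
moments: μ_R(i) = d_i·w̄ and σ²_R(i) = d_i·s²_w·(M − d_i)/(M − 1), with
d_i the degree, M the edge count, and w̄, s²_w the population mean and
variance of the weights. The two routes act as mutual oracles and agree
to |Δ| < 0.1 at 10,000 shuffles. Degenerate nulls (σ_R = 0: all weights
equal, or d_i = M) give topS = 0 — no specificity information — rather
than NaN. topS_transf = 1/(1 + e^(−topS)) maps scores into (0, 1) for
cross-network rank comparisons. When module genes are compared across
networks, genes absent from a network are scored 0 (absence from the
positive-specificity subgraph carries no evidence of influence).

**Network similarity.** Shared-edge similarity is the Spearman
correlation of weights over edges present in both networks; topology
similarity the Spearman correlation of topS_transf over shared nodes.
Pairs with fewer than 3 shared edges/nodes are *undefined*, encoded as
None rather than 0, because 0 is a meaningful correlation. Edges
present in only one induced subgraph are excluded — a rank correlation
needs paired observations.

**Gene-set connectivity.** C(S) sums the weights of edges internal to
S ∩ V and divides by |S ∩ V| (per-gene normalization keeps sets with
different network coverage comparable; `norm="sum"` and `"per_pair"`
are available). Significance comes from uniformly subsampling
|S ∩ V| genes from the network's nodes — uniform, not degree-matched,
following the stated procedure; the empirical p carries the +1
correction and is never 0. Scaled connectivity standardizes the
per-cell-type z-scores to mean 0, s.d. 1 across cell types, so the
most set-cohesive cell type attains the maximum.

**Enrichment.** Upper-tail hypergeometric p per gene set with BH
q-values across the tested sets. The default universe is the caller's
choice; the analysis scripts condition on the reference gene universe.
The closed-form p matches exhaustive enumeration on all universes with
N ≤ 12.

**RWR prioritization.** p^{t+1} = (1 − γ)·W·p^t + γ·p⁰ on the
column-normalized weighted adjacency, γ = 0.5, iterated until the L1
difference falls below 1e-10. p⁰ is uniform over the seed genes
(weighting is a free choice; uniform is neutral). Seed genes are
excluded from the candidate ranking but reported separately. Isolated
nodes receive a unit self-loop purely to keep W column-stochastic; they
can never draw probability from the seeds. The iterative solution is
checked against the direct solve of (I − (1 − γ)W)p = γp⁰ to L1 ≤ 1e-8.

**Network performance.** Gene-set recovery: split S ∩ V into seeds and
held-out positives (fraction 0.5, 10–12 repeats), rank non-seed genes
by RWR, score AUPRC with held-out members as positives and all other
non-seed genes as negatives. Null networks are degree-preserving
double-edge rewirings with the weight multiset randomly reassigned; the
same recovery splits are evaluated on the true network and every null
(paired comparison, lower variance). Performance is the robust z,
(AUPRC − median(null))/(1.4826·MAD(null)); gain is
(AUPRC − median(null))/median(null).

## Synthetic data

The generator provides the ground truth the analysis stages are tested
against; the defaults are the study conditions.

* **Reference network**: preferential attachment seeded with a single
  edge, m = round(mean_degree/2) attachments per node (so |E| =
  1 + m(n − 2)); a Poisson configuration-model alternative keeps the
  largest component. Study scale: 10,000 genes, mean degree 6 — large
  enough that 20 planted genes sit in the top 0.2% of the
  rank-inverse-normal map, which is what gives the per-network BH
  step-up the resolution to keep module-internal edges at q ≤ 0.05.
* **Counts**: NB with variance μ + φμ² (φ = 0.3 by default, ordinary
  UMI overdispersion), per-cell lognormal depth factors (σ = 0.3)
  around `depth_mean = 5` (≈ 11,000 UMIs/cell at this gene count),
  per-gene baseline log-means ~ Normal(−2, 1).
* **Planted signal**: one connected module per cell type (grown by
  randomized BFS on the reference, disjoint across cell types),
  up-regulated by log2FC δ = 2 in its cell type; 3 cell types × 500
  cells. Modules are connected subgraphs, not random gene sets, because
  the downstream premise under test is that functional gene sets form
  cohesive network neighborhoods.
* **Not emulated**: batch effects, doublets, ambient RNA,
  zero-inflation beyond NB zeros, graded specificity in background
  genes. The last point matters for interpretation: real tissues give
  SCINET-style networks with thousands of edges per cell type, while
  this simulation's background is exactly null, so significant networks
  are small and module-dominated. Passing tests demonstrate correctness
  and parameter recovery of the statistics, not realistic network
  sizes.

## Numerical choices and edge cases

* Welch denominator of 0 with unequal means → tranS = ±50 (finite cap
  preserving order); means equal to double precision (relative 1e-9,
  absorbing cancellation in the moment sums) → tranS = 0.
* Ties in ranks: average rank everywhere; gene-symbol tie-break in all
  orderings (top-k sets, hub lists, RWR rankings), making every output
  deterministic.
* Percentile ranks ascend (rank 1 = lowest score), so the most specific
  gene has PR = 1 and log2(PR_topS/PR_tranS) > 0 flags genes with
  network influence beyond their expression rank.
* Rewiring: 10×|E| attempted swaps by default; 30×|E| wherever a
  rewired network is itself the object under evaluation (the null
  self-consistency analysis), because incomplete mixing leaves the
  first rewiring closer to the clustered base graph than its own nulls
  and biases the gain a few percent negative.
* All stochastic stages take explicit integer seeds and log them;
  identical seeds give bit-identical outputs (NumPy Generator
  semantics).

## Validation scales

The self-checks run at desk scale, chosen so each completes in minutes
on one core: 50 random graphs ≤ 200 nodes for the RWR oracle; 200-node
networks with 10,000 reshuffles for the topS oracle; a 300-node network
with 200 + 500 random sets for permutation calibration; the
10,000-gene pipeline above for end-to-end recovery; a 300-gene
two-replicate panel for similarity structure; and a 500-node base
network, 80-gene set, 20 trials × 20 nulls for the null
self-consistency of the performance score.

## Known limitations

* The edge statistic is a documented variant, not a reimplementation of
  the SCINET subsampling ensemble; absolute edge weights are therefore
  not comparable to SCINET's, though rankings behave analogously.
* Uniform (not degree-matched) connectivity nulls inherit a known bias:
  high-degree gene sets look cohesive partly through degree. The
  statistic follows the stated procedure; degree-aware nulls can be
  built from `degree_preserving_rewire` if needed.
* With a single sample per dataset, the `sample` field is carried but
  unused; per-sample networks are out of scope.
* Hypergeometric enrichment treats gene sets as flat (no ontology
  ancestry propagation).
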