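"""Synthetic reference networks and labeled UMI count matrices with
planted cell-type-specific modules.

The generator provides ground truth for every downstream stage: a
reference interactome, a sparse negative-binomial count matrix whose
cell types each over-express one planted gene module, and gene sets
(the planted modules plus size-matched random sets). Each planted
module is grown as a *connected* subgraph of the reference, so that
reconstruction, connectivity deconvolution, and propagation all have a
recoverable signal — mirroring the premise that disease genes form
cohesive network neighborhoods.

Count model: counts[c, g] ~ NB with mean
``depth_c * exp(baseline_log_mean[g] + ln(2) * delta * 1[g in module of
cell_type(c)])`` and variance ``mu + phi * mu**2`` (phi =
``nb_dispersion``). Per-cell depth factors are lognormal
(sigma = 0.3 on the log scale) around ``depth_mean``, emulating
library-size variation. No zero-inflation beyond the NB zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    Edge,
    ExpressionDataset,
    GeneSet,
    ReferenceInteractome,
    ValidationError,
    canonical_edge,
)

logger = logging.getLogger("ctinet")

DEPTH_LOG_SIGMA = 0.3  # lognormal sigma of per-cell library-size factors
BASELINE_MU0 = -2.0  # baseline_log_mean ~ Normal(mu0, sigma0)
BASELINE_SIGMA0 = 1.0


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    planted_modules: dict[str, set[str]]  # cell type -> genes
    module_log2fc: float
    baseline_log_mean: dict[str, float]
    nb_dispersion: float
    module_subgraph_edges: dict[str, set[Edge]]  # cell type -> induced reference edges


def _gene_labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def generate_reference_network(
    n_genes: int,
    mean_degree: float,
    model: str = "preferential_attachment",
    seed: int = 0,
) -> ReferenceInteractome:
    """Generate a connected simple reference graph at desk scale.

    ``preferential_attachment`` seeds the graph with a single edge and
    attaches each new node to m = round(mean_degree / 2) distinct
    existing nodes with probability proportional to degree, giving
    |E| = 1 + m*(n - 2) (= 2n - 3 for m = 2). ``configuration`` draws
    Poisson degrees, simplifies, and keeps the largest component.
    """
    if n_genes < 10:
        raise ValidationError(f"n_genes must be >= 10, got {n_genes}")
    if mean_degree < 1:
        raise ValidationError(f"mean_degree must be >= 1, got {mean_degree}")
    rng = np.random.default_rng(seed)
    labels = _gene_labels(n_genes)
    logger.info("generate_reference_network: model=%s seed=%d", model, seed)

    if model == "preferential_attachment":
        m = max(1, int(round(mean_degree / 2)))
        if m >= n_genes:
            raise ValidationError("attachment count must be below n_genes")
        edges: set[Edge] = {canonical_edge(labels[0], labels[1])}
        # repeated-endpoints list: node appears once per incident edge
        endpoint_pool = [0, 1]
        for k in range(2, n_genes):
            targets: set[int] = set()
            while len(targets) < min(m, k):
                pick = endpoint_pool[rng.integers(len(endpoint_pool))]
                targets.add(pick)
            for t in targets:
                edges.add(canonical_edge(labels[k], labels[t]))
                endpoint_pool.extend((k, t))
        nodes = set(labels)
    elif model == "configuration":
        import networkx as nx

        degrees = rng.poisson(mean_degree, size=n_genes).clip(min=1)
        if degrees.sum() % 2:
            degrees[0] += 1
        g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31 - 1)))
        g = nx.Graph(g)  # collapse multi-edges
        g.remove_edges_from(nx.selfloop_edges(g))
        giant = max(nx.connected_components(g), key=len)
        dropped = n_genes - len(giant)
        if dropped:
            logger.info("configuration model: kept largest component, dropped %d nodes", dropped)
        keep = sorted(giant)
        relabel = {old: labels[i] for i, old in enumerate(keep)}
        edges = {canonical_edge(relabel[a], relabel[b]) for a, b in g.subgraph(giant).edges()}
        nodes = set(relabel.values())
    else:
        raise ValidationError(f"unknown model {model!r}")

    return ReferenceInteractome(nodes=nodes, edges=edges, name=f"synthetic-{model}").validate()


def _grow_connected_module(
    adjacency: dict[str, list[str]],
    size: int,
    forbidden: set[str],
    rng: np.random.Generator,
    max_tries: int = 100,
) -> set[str]:
    """Grow a connected node set of the requested size by randomized BFS,
    avoiding ``forbidden`` nodes."""
    candidates = [g for g in adjacency if g not in forbidden]
    for _ in range(max_tries):
        start = candidates[rng.integers(len(candidates))]
        module = {start}
        frontier = [start]
        while frontier and len(module) < size:
            node = frontier.pop(rng.integers(len(frontier)))
            nbrs = [n for n in adjacency[node] if n not in module and n not in forbidden]
            rng.shuffle(nbrs)
            for n in nbrs:
                if len(module) >= size:
                    break
                module.add(n)
                frontier.append(n)
        if len(module) == size:
            return module
    raise ValidationError(
        f"could not grow a disjoint connected module of size {size} "
        f"after {max_tries} attempts"
    )


def generate_expression(
    reference: ReferenceInteractome,
    cell_types: list[tuple[str, int]],
    module_size: int = 20,
    module_log2fc: float = 2.0,
    nb_dispersion: float = 0.3,
    depth_mean: float = 5.0,
    seed: int = 0,
    modules: dict[str, set[str]] | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate a labeled UMI count matrix over the reference gene universe.

    One connected, cell-type-disjoint module of ``module_size`` genes is
    planted per cell type (or taken from ``modules`` if given, e.g. to
    hold the signal fixed across replicate "tumor types") and
    up-regulated by ``module_log2fc`` (log2 units) in its cell type.
    """
    if module_size * len(cell_types) > reference.n_nodes:
        raise ValidationError("modules do not fit in the reference gene universe")
    if nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    logger.info("generate_expression: seed=%d delta=%.3g", seed, module_log2fc)

    genes = sorted(reference.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    if modules is None:
        adjacency: dict[str, list[str]] = {g: [] for g in genes}
        for a, b in reference.edges:
            adjacency[a].append(b)
            adjacency[b].append(a)
        modules = {}
        used: set[str] = set()
        for label, _ in cell_types:
            mod = _grow_connected_module(adjacency, module_size, used, rng)
            modules[label] = mod
            used |= mod
    else:
        modules = {k: set(v) for k, v in modules.items()}

    module_edges = {
        label: {e for e in reference.edges if e[0] in mod and e[1] in mod}
        for label, mod in modules.items()
    }

    baseline = rng.normal(BASELINE_MU0, BASELINE_SIGMA0, size=n_genes)
    log2 = np.log(2.0)

    blocks = []
    cell_ids: list[str] = []
    labels_per_cell: list[str] = []
    for label, n_cells in cell_types:
        if n_cells < 2:
            raise ValidationError(f"cell type {label!r} needs >= 2 cells")
        depth = depth_mean * np.exp(rng.normal(0.0, DEPTH_LOG_SIGMA, size=n_cells))
        log_mu = baseline.copy()
        for g in modules.get(label, ()):
            log_mu[gene_idx[g]] += log2 * module_log2fc
        mu = depth[:, None] * np.exp(log_mu)[None, :]
        r = 1.0 / nb_dispersion
        p = 1.0 / (1.0 + nb_dispersion * mu)
        counts = rng.negative_binomial(r, p)
        blocks.append(sp.csr_matrix(counts))
        cell_ids.extend(f"{label}_c{i + 1:05d}" for i in range(n_cells))
        labels_per_cell.extend([label] * n_cells)

    counts = sp.vstack(blocks, format="csr").astype(np.int64)
    cell_type = pd.Series(labels_per_cell, index=cell_ids, name="cell_type")
    sample = pd.Series(["sample1"] * len(cell_ids), index=cell_ids, name="sample")
    ds = ExpressionDataset(
        counts=counts, gene_ids=genes, cell_ids=cell_ids, cell_type=cell_type, sample=sample
    ).validate()
    truth = SyntheticTruth(
        planted_modules=modules,
        module_log2fc=module_log2fc,
        baseline_log_mean={g: float(baseline[gene_idx[g]]) for g in genes},
        nb_dispersion=nb_dispersion,
        module_subgraph_edges=module_edges,
    )
    return ds, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    reference: ReferenceInteractome,
    n_random: int = 0,
    seed: int = 0,
) -> list[GeneSet]:
    """One GeneSet per planted module plus size-matched uniform random sets."""
    rng = np.random.default_rng(seed)
    genes = sorted(reference.nodes)
    sets = [
        GeneSet(name=f"module_{label}", description="planted module", genes=set(mod)).validate()
        for label, mod in sorted(truth.planted_modules.items())
    ]
    size = len(next(iter(truth.planted_modules.values()))) if truth.planted_modules else 0
    for i in range(n_random):
        pick = rng.choice(len(genes), size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"random_{i + 1:03d}",
                description="size-matched random set",
                genes={genes[j] for j in pick},
            ).validate()
        )
    return sets
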