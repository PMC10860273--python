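"""Shared fixtures: tiny hand-built networks and one session-scoped
end-to-end synthetic pipeline reused by the recovery and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import ctinet as ct

# study conditions of the end-to-end parameter-recovery runs
PIPELINE = dict(
    n_genes=10_000,
    mean_degree=6.0,
    cell_types=[("A", 500), ("B", 500), ("C", 500)],
    module_size=20,
    module_log2fc=2.0,
    seed=20_260_919,
)


def random_weighted_network(
    n_nodes: int, mean_degree: float, seed: int, weight_sigma: float = 0.5
) -> ct.CellTypeNetwork:
    """Random simple graph with lognormal edge weights (test substrate)."""
    ref = ct.generate_reference_network(n_nodes, mean_degree, seed=seed)
    rng = np.random.default_rng(seed + 1)
    edges = sorted(ref.edges)
    w = rng.lognormal(0.0, weight_sigma, size=len(edges))
    return ct.network_from_edges(
        f"random{n_nodes}", [(a, b, float(x)) for (a, b), x in zip(edges, w)]
    )


@dataclass
class Pipeline:
    reference: ct.ReferenceInteractome
    expr: ct.ExpressionDataset
    truth: ct.SyntheticTruth
    profile: ct.SpecificityProfile
    networks: dict[str, ct.CellTypeNetwork]  # q <= 0.05 (the deliverable networks)
    dense: dict[str, ct.CellTypeNetwork]  # all positive-specificity edges
    module_sets: dict[str, ct.GeneSet]


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    """Simulate + reconstruct once for every end-to-end test."""
    ref = ct.generate_reference_network(
        PIPELINE["n_genes"], PIPELINE["mean_degree"], seed=PIPELINE["seed"]
    )
    expr, truth = ct.generate_expression(
        ref,
        PIPELINE["cell_types"],
        module_size=PIPELINE["module_size"],
        module_log2fc=PIPELINE["module_log2fc"],
        seed=PIPELINE["seed"] + 1,
    )
    networks, profile = ct.reconstruct_all(ref, expr)
    dense_cfg = ct.RunConfig(alpha_edge_q=1.0)
    dense = {
        c: ct.reconstruct_cell_type_network(ref, profile, c, dense_cfg) for c in networks
    }
    sets = ct.generate_gene_sets(truth, ref, n_random=0, seed=PIPELINE["seed"] + 2)
    module_sets = {s.name.removeprefix("module_"): s for s in sets}
    return Pipeline(
        reference=ref,
        expr=expr,
        truth=truth,
        profile=profile,
        networks=networks,
        dense=dense,
        module_sets=module_sets,
    )


@pytest.fixture
def triangle() -> ct.CellTypeNetwork:
    """A-B (1), A-C (2), B-C (3)."""
    return ct.network_from_edges("tri", [("A", "B", 1.0), ("A", "C", 2.0), ("B", "C", 3.0)])


@pytest.fixture
def path_net() -> ct.CellTypeNetwork:
    """Path A-B-C with weights 10 and 1."""
    return ct.network_from_edges("path", [("A", "B", 10.0), ("B", "C", 1.0)])
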