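"""Pairwise similarity between cell-type networks.

Two metrics: shared-edge similarity (Spearman correlation of the
weights of edges present in both networks) and topology similarity
(Spearman correlation of topS_transf over shared nodes). Pairs with too
little overlap (< 3 shared edges / nodes) are reported as undefined
(None), never as 0 — zero is a meaningful correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .core import CellTypeNetwork, ValidationError, network_from_edges
from .topology import TopologyScores

logger = logging.getLogger("ctinet")

MIN_SHARED = 3


@dataclass
class SimilarityResult:
    network_a: str
    network_b: str
    n_shared_nodes: int
    n_shared_edges: int
    unique_to_shared_node_ratio: float | None
    unique_to_shared_edge_ratio: float | None
    edge_similarity: float | None = None
    topology_similarity: float | None = None


def shared_edge_similarity(a: CellTypeNetwork, b: CellTypeNetwork) -> float | None:
    """Spearman rho of weights over edges present in both networks."""
    shared = sorted(a.edges & b.edges)
    if len(shared) < MIN_SHARED:
        return None
    wa = [a.weight[e] for e in shared]
    wb = [b.weight[e] for e in shared]
    rho = spearmanr(wa, wb).statistic
    return None if np.isnan(rho) else float(rho)


def topology_similarity(
    a: CellTypeNetwork,
    b: CellTypeNetwork,
    scores_a: TopologyScores,
    scores_b: TopologyScores,
) -> float | None:
    """Spearman rho of topS_transf over nodes present in both networks."""
    shared = sorted(a.nodes & b.nodes)
    if len(shared) < MIN_SHARED:
        return None
    sa = [scores_a.topS_transf[g] for g in shared]
    sb = [scores_b.topS_transf[g] for g in shared]
    rho = spearmanr(sa, sb).statistic
    return None if np.isnan(rho) else float(rho)


def shared_unique_counts(a: CellTypeNetwork, b: CellTypeNetwork) -> SimilarityResult:
    """Shared/unique node and edge accounting for one network pair."""
    shared_nodes = a.nodes & b.nodes
    shared_edges = a.edges & b.edges

    def ratio(set_a: set, set_b: set, shared: set) -> float | None:
        if not shared:
            return None
        return (len(set_a - set_b) + len(set_b - set_a)) / len(shared)

    return SimilarityResult(
        network_a=a.cell_type,
        network_b=b.cell_type,
        n_shared_nodes=len(shared_nodes),
        n_shared_edges=len(shared_edges),
        unique_to_shared_node_ratio=ratio(a.nodes, b.nodes, shared_nodes),
        unique_to_shared_edge_ratio=ratio(a.edges, b.edges, shared_edges),
    )


def compare_networks(
    a: CellTypeNetwork,
    b: CellTypeNetwork,
    scores_a: TopologyScores | None = None,
    scores_b: TopologyScores | None = None,
) -> SimilarityResult:
    """Full pairwise comparison; topology similarity only if scores given."""
    res = shared_unique_counts(a, b)
    res.edge_similarity = shared_edge_similarity(a, b)
    if scores_a is not None and scores_b is not None:
        res.topology_similarity = topology_similarity(a, b, scores_a, scores_b)
    return res


def network_intersection(
    networks: list[CellTypeNetwork], weight_rule: str = "mean"
) -> CellTypeNetwork:
    """Edges present in every input network; weights combined by mean or min."""
    if len(networks) < 2:
        raise ValidationError("network_intersection needs >= 2 networks")
    if weight_rule not in ("mean", "min"):
        raise ValidationError(f"unknown weight_rule {weight_rule!r}")
    common = set.intersection(*(n.edges for n in networks))
    if not common:
        logger.warning("network intersection is empty")
    agg = np.mean if weight_rule == "mean" else np.min
    label = "intersection(" + ",".join(n.cell_type for n in networks) + ")"
    return network_from_edges(
        label,
        [(a, b, float(agg([n.weight[(a, b)] for n in networks]))) for a, b in sorted(common)],
        parent="+".join(sorted({n.parent for n in networks})),
    )
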