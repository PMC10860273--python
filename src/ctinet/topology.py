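"""Node-level topology statistics on a cell-type network.

Topological specificity topS contrasts a gene's neighborhood strength
w(i) (sum of incident edge weights) with a null that keeps the network
topology fixed and uniformly reshuffles the edge weights:

    topS(i) = (w(i) - mu_R(i)) / sigma_R(i)

The null moments are available two ways, which act as mutual oracles:
a Monte-Carlo ensemble of weight permutations, and the exact
finite-population moments of sampling d_i weights without replacement
from the M edge weights:

    mu_R(i) = d_i * wbar
    sigma_R^2(i) = d_i * s_w^2 * (M - d_i) / (M - 1)

with wbar and s_w^2 the population mean and variance of all edge
weights. Degenerate nulls (sigma_R = 0, e.g. all weights equal or
d_i = M) carry no specificity information and give topS = 0.

topS_transf(i) = 1 / (1 + exp(-topS(i))) maps topS into (0, 1) for
cross-network rank comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import CellTypeNetwork, ValidationError

logger = logging.getLogger("ctinet")


@dataclass
class TopologyScores:
    """topS and its ingredients for one network."""

    cell_type: str
    w: dict[str, float]
    mu_R: dict[str, float]
    sigma_R: dict[str, float]
    topS: dict[str, float]
    topS_transf: dict[str, float]
    n_shuffles: int | str  # number of reshuffles, or "closed_form"

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.w)
        return pd.DataFrame(
            {
                "gene": genes,
                "w": [self.w[g] for g in genes],
                "mu_R": [self.mu_R[g] for g in genes],
                "sigma_R": [self.sigma_R[g] for g in genes],
                "topS": [self.topS[g] for g in genes],
                "topS_transf": [self.topS_transf[g] for g in genes],
            }
        ).set_index("gene")

    def ranking(self) -> list[str]:
        """Genes ordered most-specific first; ties broken by symbol."""
        return sorted(self.topS, key=lambda g: (-self.topS[g], g))


def neighborhood_strength(network: CellTypeNetwork) -> dict[str, float]:
    """w(i): total weight of edges incident to each node (isolated -> 0)."""
    return network.strengths()


def topological_specificity(
    network: CellTypeNetwork,
    mode: str = "closed_form",
    n_shuffles: int = 1000,
    seed: int = 0,
) -> TopologyScores:
    """topS for every node under the edge-weight reshuffle null."""
    node_list, u, v, weights = network.edge_arrays()
    n = len(node_list)
    m = len(weights)
    strengths = np.zeros(n)
    np.add.at(strengths, u, weights)
    np.add.at(strengths, v, weights)
    degrees = np.zeros(n)
    np.add.at(degrees, u, 1)
    np.add.at(degrees, v, 1)

    if mode == "closed_form":
        if m < 2:
            warnings.warn("closed-form null needs >= 2 edges; topS set to 0 everywhere")
            mu = strengths.copy()
            sigma = np.zeros(n)
        else:
            wbar = weights.mean()
            s2 = weights.var()  # population variance
            mu = degrees * wbar
            var = degrees * s2 * (m - degrees) / (m - 1)
            sigma = np.sqrt(np.maximum(var, 0.0))
        tag: int | str = "closed_form"
    elif mode == "monte_carlo":
        if n_shuffles < 100:
            raise ValidationError("monte_carlo needs n_shuffles >= 100")
        rng = np.random.default_rng(seed)
        logger.info("topological_specificity monte_carlo: %d shuffles, seed=%d", n_shuffles, seed)
        import scipy.sparse as sp

        # node x edge incidence; strengths for all shuffles in one product
        incidence = sp.csr_matrix(
            (
                np.ones(2 * m),
                (np.concatenate([u, v]), np.concatenate([np.arange(m), np.arange(m)])),
            ),
            shape=(n, m),
        )
        perm_weights = rng.permuted(np.broadcast_to(weights, (n_shuffles, m)), axis=1)
        null_strengths = incidence @ perm_weights.T  # n x n_shuffles
        mu = null_strengths.mean(axis=1)
        sigma = null_strengths.std(axis=1, ddof=1)
        tag = n_shuffles
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        tops = (strengths - mu) / sigma
    tops[~np.isfinite(tops)] = 0.0
    tops[sigma == 0] = 0.0
    transf = 1.0 / (1.0 + np.exp(-tops))
    return TopologyScores(
        cell_type=network.cell_type,
        w=dict(zip(node_list, strengths)),
        mu_R=dict(zip(node_list, mu)),
        sigma_R=dict(zip(node_list, sigma)),
        topS=dict(zip(node_list, tops)),
        topS_transf=dict(zip(node_list, transf)),
        n_shuffles=tag,
    )


def rank_genes(scores: dict[str, float]) -> list[str]:
    """Order genes best-first by score, ties broken by gene symbol."""
    return sorted(scores, key=lambda g: (-scores[g], g))


def top_k_jaccard(ranking_a: list[str], ranking_b: list[str], k: int) -> float:
    """Jaccard index of the top-k genes of two orderings (best first)."""
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > len(ranking_a) or k > len(ranking_b):
        raise ValidationError("k exceeds ranking length")
    a, b = set(ranking_a[:k]), set(ranking_b[:k])
    return len(a & b) / len(a | b)


def percentile_rank_log2fc(
    topS: dict[str, float], tranS: dict[str, float]
) -> dict[str, float]:
    """log2 ratio of percentile ranks, PR_topS / PR_tranS.

    Percentile rank uses ascending ranks (rank 1 = lowest score) scaled
    by the gene count, so the most specific gene has PR = 1. Positive
    values flag genes with topologically specific influence beyond what
    their expression specificity predicts.
    """
    shared = sorted(set(topS) & set(tranS))
    dropped = (set(topS) | set(tranS)) - set(shared)
    if dropped:
        warnings.warn(f"{len(dropped)} genes missing from one mapping were excluded")
    if not shared:
        return {}
    g = len(shared)
    pr_top = rankdata([topS[x] for x in shared], method="average") / g
    pr_tran = rankdata([tranS[x] for x in shared], method="average") / g
    vals = np.log2(pr_top / pr_tran)
    return dict(zip(shared, vals))
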