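"""Reference-guided reconstruction of cell-type-specific networks.

Stage 1 scores every gene's transcriptional specificity per cell type
with a Welch-style statistic on log1p(CP10K)-normalized counts:

    tranS(i) = (x_ct(i) - x_else(i)) / sqrt(s2_ct(i)/n_ct + s2_else(i)/n_else)

Stage 2 maps tranS to normal scores by a rank-inverse-normal transform
within each cell type, combines the two endpoint scores of every
reference edge with a Stouffer statistic z_ij = (z_i + z_j)/sqrt(2),
converts to an upper-tail normal p-value, applies Benjamini-Hochberg
within the cell type, and keeps edges with q <= alpha and z_ij > 0,
weighted by z_ij.

The edge combiner is deliberately a closed-form Stouffer statistic
rather than a subsampling ensemble: it is deterministic, testable
against hand computation, and pluggable (``combiner=`` accepts any
function mapping two endpoint z-arrays to an edge z-array).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .core import (
    CellTypeNetwork,
    ExpressionDataset,
    ReferenceInteractome,
    ValidationError,
    network_from_edges,
)

logger = logging.getLogger("ctinet")

TRANS_CAP = 50.0  # |tranS| when both group variances vanish but means differ
CP10K = 1e4


@dataclass
class SpecificityProfile:
    """Per-gene, per-cell-type transcriptional specificity.

    ``tranS`` and ``z`` are genes x cell-types DataFrames; the group
    summary statistics entering the Welch formula are retained so any
    score can be audited.
    """

    tranS: pd.DataFrame
    z: pd.DataFrame
    n_cells: dict[str, int]
    group_mean: pd.DataFrame  # x_celltype(i)
    other_mean: pd.DataFrame  # x_else(i)
    group_var: pd.DataFrame
    other_var: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.tranS.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.tranS.columns)


def normalize_log1p_cp10k(counts: sp.csr_matrix) -> sp.csr_matrix:
    """Depth-normalize to 10,000 counts per cell, then log1p."""
    libsize = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    if np.any(libsize == 0):
        logger.warning("%d cells have zero total counts", int((libsize == 0).sum()))
        libsize[libsize == 0] = 1.0
    scaled = counts.multiply((CP10K / libsize)[:, None]).tocsr()
    scaled.data = np.log1p(scaled.data)
    return scaled


def welch_specificity(
    x: sp.csr_matrix | np.ndarray, labels: np.ndarray
) -> tuple[pd.DataFrame, dict[str, int], dict[str, pd.DataFrame]]:
    """Welch statistic of each column (gene) for each label vs the rest.

    ``x`` is an already-normalized cells x genes matrix. Returns the
    tranS DataFrame plus group sizes and the retained summary stats.
    Zero-variance guard: if both group variances vanish, tranS is 0 for
    equal means and +/- TRANS_CAP otherwise.
    """
    labels = np.asarray(labels)
    cell_types = sorted(pd.unique(labels))
    if len(cell_types) < 2:
        raise ValidationError("need >= 2 cell types")
    x = sp.csr_matrix(x) if not sp.issparse(x) else x.tocsr()
    n_cells_total, n_genes = x.shape

    x2 = x.multiply(x).tocsr()
    total_sum = np.asarray(x.sum(axis=0)).ravel()
    total_sq = np.asarray(x2.sum(axis=0)).ravel()

    cols = {}
    stats: dict[str, dict[str, np.ndarray]] = {}
    n_cells: dict[str, int] = {}
    for ct in cell_types:
        mask = labels == ct
        n1 = int(mask.sum())
        n2 = n_cells_total - n1
        if n1 < 2 or n2 < 2:
            raise ValidationError(f"cell type {ct!r} needs >= 2 cells in and out of group")
        s1 = np.asarray(x[mask].sum(axis=0)).ravel()
        q1 = np.asarray(x2[mask].sum(axis=0)).ravel()
        m1 = s1 / n1
        m2 = (total_sum - s1) / n2
        v1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
        v2 = np.maximum((total_sq - q1) - n2 * m2**2, 0.0) / (n2 - 1)
        denom = np.sqrt(v1 / n1 + v2 / n2)
        diff = m1 - m2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        degenerate = denom == 0
        t[degenerate] = np.sign(diff[degenerate]) * TRANS_CAP
        # equal means (to double precision) always give tranS = 0; the
        # relative guard absorbs cancellation noise in the moment sums
        equal = np.isclose(m1, m2, rtol=1e-9, atol=0.0)
        t[equal] = 0.0
        cols[ct] = t
        n_cells[ct] = n1
        stats[ct] = {"m1": m1, "m2": m2, "v1": v1, "v2": v2}
    tranS = pd.DataFrame(cols)
    summaries = {
        key: pd.DataFrame({ct: stats[ct][key] for ct in cell_types})
        for key in ("m1", "m2", "v1", "v2")
    }
    return tranS, n_cells, summaries


def compute_transcriptional_specificity(expr: ExpressionDataset) -> SpecificityProfile:
    """tranS and its rank-inverse-normal scores for every gene x cell type."""
    x = normalize_log1p_cp10k(expr.counts)
    labels = expr.cell_type.loc[expr.cell_ids].to_numpy()
    tranS, n_cells, summaries = welch_specificity(x, labels)
    tranS.index = expr.gene_ids
    z = pd.DataFrame(
        {ct: rank_inverse_normal(tranS[ct].to_numpy()) for ct in tranS.columns},
        index=expr.gene_ids,
    )
    for df in summaries.values():
        df.index = expr.gene_ids
    return SpecificityProfile(
        tranS=tranS,
        z=z,
        n_cells=n_cells,
        group_mean=summaries["m1"],
        other_mean=summaries["m2"],
        group_var=summaries["v1"],
        other_var=summaries["v2"],
    )


def rank_inverse_normal(scores: np.ndarray) -> np.ndarray:
    """Map scores to normal quantiles: z_i = Phi^-1((r_i - 0.5)/G).

    Ranks are 1-based with average ranks for ties, so an all-equal
    input maps to exactly zero. Monotone in the input.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("rank_inverse_normal requires finite scores")
    r = rankdata(scores, method="average")
    return norm.ppf((r - 0.5) / len(scores))


def stouffer_combiner(z_i: np.ndarray, z_j: np.ndarray) -> np.ndarray:
    """Default edge statistic: (z_i + z_j) / sqrt(2)."""
    return (z_i + z_j) / np.sqrt(2.0)


def reconstruct_cell_type_network(
    reference: ReferenceInteractome,
    profile: SpecificityProfile,
    cell_type: str,
    cfg: RunConfig | None = None,
    combiner: Callable[[np.ndarray, np.ndarray], np.ndarray] = stouffer_combiner,
) -> CellTypeNetwork:
    """Carve the cell-type-specific network out of the reference.

    Only reference edges with both endpoints measured are tested; the
    result's edge set is always a subset of the reference edge set.
    """
    cfg = (cfg or RunConfig()).validate()
    if cell_type not in profile.cell_types:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    n = profile.n_cells[cell_type]
    if n < cfg.min_cells:
        raise ValidationError(
            f"cell type {cell_type!r} has {n} cells; a minimum of {cfg.min_cells} "
            "cells is required for network construction"
        )
    z = profile.z[cell_type]
    measured = set(profile.genes)
    edges = sorted(e for e in reference.edges if e[0] in measured and e[1] in measured)
    if not edges:
        logger.warning("no reference edges with measured endpoints for %s", cell_type)
        return network_from_edges(cell_type, [], parent=reference.name)

    z_i = z.loc[[a for a, _ in edges]].to_numpy()
    z_j = z.loc[[b for _, b in edges]].to_numpy()
    z_edge = combiner(z_i, z_j)
    p = norm.sf(z_edge)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    keep = (q <= cfg.alpha_edge_q) & (z_edge > 0)
    logger.info(
        "reconstruct %s: %d/%d edges retained at q<=%g", cell_type, int(keep.sum()),
        len(edges), cfg.alpha_edge_q,
    )
    kept = [
        (a, b, w) for (a, b), w, k in zip(edges, z_edge, keep) if k
    ]
    q_map = {e: float(qv) for e, qv, k in zip(edges, q, keep) if k}
    net = network_from_edges(cell_type, kept, parent=reference.name, q_value=q_map)
    return net.validate(reference)


def reconstruct_all(
    reference: ReferenceInteractome,
    expr: ExpressionDataset,
    cfg: RunConfig | None = None,
) -> tuple[dict[str, CellTypeNetwork], SpecificityProfile]:
    """Profile once, then reconstruct every cell type meeting min_cells."""
    cfg = (cfg or RunConfig()).validate()
    profile = compute_transcriptional_specificity(expr)
    networks = {}
    for ct in profile.cell_types:
        if profile.n_cells[ct] < cfg.min_cells:
            logger.info("skipping %s: %d cells < min_cells=%d", ct, profile.n_cells[ct], cfg.min_cells)
            continue
        networks[ct] = reconstruct_cell_type_network(reference, profile, ct, cfg)
    return networks, profile
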