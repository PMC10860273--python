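"""Domain types shared by every stage of the pipeline.

The pipeline operates on four kinds of objects: a reference interactome
(an undirected, optionally confidence-weighted graph over gene symbols),
a labeled single-cell expression dataset, gene sets, and the cell-type
networks carved out of the reference. Gene identifiers are opaque,
case-sensitive strings; undirected edges are canonicalized as
lexicographically ordered pairs so that hashing and diffing are
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("ctinet")

Edge = tuple[str, str]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def canonical_edge(a: str, b: str) -> Edge:
    """Return the unordered pair (a, b) in lexicographic order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferenceInteractome:
    """Undirected weighted graph over gene symbols.

    The global prior from which all cell-type-specific networks are
    carved. ``prior_weight`` (e.g. a database confidence score) is
    carried through IO but does not enter reconstruction.
    """

    nodes: set[str]
    edges: set[Edge]
    prior_weight: dict[Edge, float] | None = None
    name: str = "reference"

    def validate(self) -> "ReferenceInteractome":
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if (a, b) != canonical_edge(a, b):
                raise ValidationError(f"edge ({a!r}, {b!r}) not canonical")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge endpoint missing from nodes: ({a!r}, {b!r})")
        if self.prior_weight is not None:
            for e, w in self.prior_weight.items():
                if e not in self.edges:
                    raise ValidationError(f"prior weight for unknown edge {e!r}")
                if not (math.isfinite(w) and w >= 0):
                    raise ValidationError(f"prior weight for {e!r} is {w!r}")
        return self

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.name)
        g.add_nodes_from(self.nodes)
        for a, b in self.edges:
            w = self.prior_weight.get((a, b)) if self.prior_weight else None
            if w is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, weight=w)
        return g


@dataclass
class ExpressionDataset:
    """Sparse cells x genes UMI count matrix with per-cell labels."""

    counts: sp.csr_matrix  # cells x genes, non-negative integers
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: pd.Series  # index: cell_id
    sample: pd.Series  # index: cell_id

    def validate(self) -> "ExpressionDataset":
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if not np.all(np.isfinite(self.counts.data)):
            raise ValidationError("non-finite counts")
        if np.any(self.counts.data != np.round(self.counts.data)):
            raise ValidationError("non-integer counts")
        missing = [c for c in self.cell_ids if c not in self.cell_type.index]
        if missing:
            raise ValidationError(f"cells without a cell-type label: {missing[:5]}")
        return self

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cells_per_type(self) -> dict[str, int]:
        labels = self.cell_type.loc[self.cell_ids]
        return labels.value_counts().to_dict()

    def to_anndata(self):
        """Convenience view as an AnnData (cells x genes)."""
        import anndata as ad

        obs = pd.DataFrame(
            {
                "cell_type": self.cell_type.loc[self.cell_ids].values,
                "sample": self.sample.loc[self.cell_ids].values,
            },
            index=self.cell_ids,
        )
        return ad.AnnData(X=self.counts.copy(), obs=obs, var=pd.DataFrame(index=self.gene_ids))


@dataclass
class GeneSet:
    """Named set of gene symbols (one GMT line)."""

    name: str
    description: str
    genes: set[str]

    def validate(self) -> "GeneSet":
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        return self


@dataclass
class CellTypeNetwork:
    """Weighted subgraph of the reference specific to one cell type.

    ``weight`` holds the interaction strength w_ij (positive by
    construction); ``q_value`` the BH-adjusted edge significance from
    reconstruction (absent for synthetic/derived networks).
    """

    cell_type: str
    nodes: set[str]
    edges: set[Edge]
    weight: dict[Edge, float]
    parent: str = "reference"
    q_value: dict[Edge, float] | None = None

    def validate(self, reference: ReferenceInteractome | None = None) -> "CellTypeNetwork":
        for e in self.edges:
            a, b = e
            if a == b or e != canonical_edge(a, b):
                raise ValidationError(f"bad edge {e!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValidationError(f"edge endpoint missing from nodes: {e!r}")
            w = self.weight.get(e)
            if w is None or not math.isfinite(w) or w <= 0:
                raise ValidationError(f"edge {e!r} has weight {w!r}")
            if reference is not None and e not in reference.edges:
                raise ValidationError(f"edge {e!r} not in reference")
        if self.q_value is not None:
            for e, q in self.q_value.items():
                if not (0.0 <= q <= 1.0):
                    raise ValidationError(f"q-value {q!r} for edge {e!r}")
        return self

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_arrays(self) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
        """Return (node_list, u_idx, v_idx, weights) with a stable node order."""
        node_list = sorted(self.nodes)
        idx = {g: i for i, g in enumerate(node_list)}
        edges = sorted(self.edges)
        u = np.array([idx[a] for a, _ in edges], dtype=np.int64)
        v = np.array([idx[b] for _, b in edges], dtype=np.int64)
        w = np.array([self.weight[e] for e in edges], dtype=float)
        return node_list, u, v, w

    def strengths(self) -> dict[str, float]:
        """Weighted degree (sum of incident edge weights); isolated nodes -> 0."""
        s = {g: 0.0 for g in self.nodes}
        for (a, b), w in self.weight.items():
            s[a] += w
            s[b] += w
        return s

    def degrees(self) -> dict[str, int]:
        d = {g: 0 for g in self.nodes}
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(name=self.cell_type)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, weight=self.weight[e])
        return g


def network_from_edges(
    cell_type: str,
    weighted_edges: Iterable[tuple[str, str, float]],
    parent: str = "reference",
    q_value: Mapping[Edge, float] | None = None,
    extra_nodes: Iterable[str] = (),
) -> CellTypeNetwork:
    """Build a validated CellTypeNetwork from (a, b, w) triples."""
    nodes: set[str] = set(extra_nodes)
    edges: set[Edge] = set()
    weight: dict[Edge, float] = {}
    for a, b, w in weighted_edges:
        e = canonical_edge(a, b)
        nodes.update(e)
        edges.add(e)
        weight[e] = float(w)
    net = CellTypeNetwork(
        cell_type=cell_type,
        nodes=nodes,
        edges=edges,
        weight=weight,
        parent=parent,
        q_value=dict(q_value) if q_value is not None else None,
    )
    return net.validate()
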